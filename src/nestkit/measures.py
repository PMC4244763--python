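"""The seven nestedness measures and automatic direction detection.

Binary measures
---------------
NODF
    Nestedness by overlap and decreasing fill: mean percentage overlap over
    ordered pairs of lines with strictly decreasing fill.
MD
    Manhattan distance: total taxicab distance of presences from the
    top-left corner of the sorted matrix.
NTC
    Nestedness temperature: normalised squared diagonal distances of
    unexpected presences/absences about an isocline of perfect order,
    minimised over arrangements (see :mod:`nestkit._ntc`).
JDM
    Ratio of observed pairwise neighbourhood overlap to its
    configuration-model expectation; order-invariant.
BR
    Discrepancy: number of presences lying outside the maximally packed
    form of each row.

Weighted measures
-----------------
WNODF
    Weighted NODF: overlap terms require strictly smaller positive weights
    in the sparser line.
SR
    Spectral radius of the symmetric bipartite adjacency embedding,
    equal to the largest singular value of the biadjacency matrix;
    order-invariant and defined for binary and weighted data alike.

Because some measures grow and others shrink with increasing nestedness,
the package orients every measure empirically: it scores a reference
highly-nested matrix and a reference checkerboard (equal fill and equal
element sum) and records which direction means "more nested"
(:func:`detect_direction`).  Any newly registered measure is oriented the
same way with no code changes elsewhere.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass

import numpy as np

from ._ntc import temperature_of
from .core_io import BipartiteMatrix
from .sorting import NestedConfiguration, degree_sort, identity_configuration, ntc_sort

__all__ = [
    "Direction",
    "MeasureScore",
    "BINARY_MEASURES",
    "WEIGHTED_MEASURES",
    "ALL_MEASURES",
    "nodf",
    "wnodf",
    "manhattan_distance",
    "temperature",
    "jdm",
    "discrepancy",
    "spectral_radius",
    "direction_fixtures",
    "detect_direction",
    "measure_score",
    "score_matrix",
]

BINARY_MEASURES = ("NODF", "MD", "NTC", "JDM", "BR")
WEIGHTED_MEASURES = ("WNODF", "SR")
ALL_MEASURES = BINARY_MEASURES + WEIGHTED_MEASURES
#: measures whose value does not depend on row/column ordering
ORDER_INVARIANT = ("JDM", "SR")


class Direction(enum.Enum):
    HIGHER_IS_MORE_NESTED = "higher_is_more_nested"
    LOWER_IS_MORE_NESTED = "lower_is_more_nested"


@dataclass(frozen=True)
class MeasureScore:
    measure_id: str
    value: float
    direction: Direction


def _require_binary(m: BipartiteMatrix, name: str) -> None:
    if not m.is_binary:
        raise ValueError(
            f"{name} is defined for binary matrices only; binarise the input "
            "or use a weighted measure"
        )


# -- NODF / WNODF ---------------------------------------------------------


def _nodf_axis_sum(lines: np.ndarray) -> float:
    """Sum of paired NODF terms over ordered line pairs (k before l)."""
    fills = np.count_nonzero(lines, axis=1).astype(float)
    shared = (lines != 0).astype(float) @ (lines != 0).astype(float).T
    k, l = np.triu_indices(lines.shape[0], k=1)
    decreasing = fills[k] > fills[l]
    terms = np.where(decreasing, 100.0 * shared[k, l] / np.where(fills[l] > 0, fills[l], 1.0), 0.0)
    return float(terms[decreasing & (fills[l] > 0)].sum())


def nodf(m: BipartiteMatrix) -> float:
    """NODF of a binary matrix already in its sorted arrangement, in [0, 100].

    For each ordered pair of columns (k before l) with strictly decreasing
    fill, the paired term is 100 * |shared rows| / fill(l); likewise for
    row pairs.  The score is the grand sum divided by the number of pairs,
    n(n-1)/2 + m(m-1)/2.  Pairs of equal fill contribute zero.
    """
    _require_binary(m, "NODF")
    n, mm = m.shape
    n_pairs = n * (n - 1) // 2 + mm * (mm - 1) // 2
    if n_pairs == 0:
        raise ValueError("NODF needs at least two rows or two columns")
    total = _nodf_axis_sum(m.values) + _nodf_axis_sum(m.values.T)
    return total / n_pairs


def _wnodf_axis_sum(lines: np.ndarray) -> float:
    fills = np.count_nonzero(lines, axis=1).astype(float)
    total = 0.0
    for k in range(lines.shape[0] - 1):
        for l in range(k + 1, lines.shape[0]):
            if fills[k] > fills[l] > 0:
                wins = np.count_nonzero((lines[l] > 0) & (lines[l] < lines[k]))
                total += 100.0 * wins / fills[l]
    return total


def wnodf(m: BipartiteMatrix) -> float:
    """Weighted NODF of a sorted non-negative matrix, in [0, 100].

    A column pair (k before l) with fill(k) > fill(l) contributes
    100 * #{rows: 0 < w(row, l) < w(row, k)} / fill(l); rows symmetric.
    On binary data the strict inequality never holds, so WNODF is 0.
    """
    n, mm = m.shape
    n_pairs = n * (n - 1) // 2 + mm * (mm - 1) // 2
    if n_pairs == 0:
        raise ValueError("WNODF needs at least two rows or two columns")
    total = _wnodf_axis_sum(m.values) + _wnodf_axis_sum(m.values.T)
    return total / n_pairs


# -- Manhattan distance ---------------------------------------------------


def manhattan_distance(m: BipartiteMatrix) -> float:
    """Total taxicab distance of presences from the top-left corner.

    MD = sum over nonzero cells of (i - 1) + (j - 1) with 1-based indices;
    lower values mean more nested (mass packed into the corner).  Computed
    on the arrangement as given — sort first.
    """
    _require_binary(m, "MD")
    i, j = np.nonzero(m.values)
    return float(np.sum(i + j))


# -- Temperature ----------------------------------------------------------


def temperature(m: BipartiteMatrix, sort: bool = True) -> float:
    """Nestedness temperature (0 = perfectly ordered, ~100 = disordered).

    Binarises, finds the temperature-minimal arrangement (deterministic
    hill-climb from the degree sort) and returns its temperature.  With
    ``sort=False`` the matrix is scored exactly as arranged.
    """
    mb = m.binarised()
    if m.n_rows * m.n_cols < 4:
        raise ValueError("temperature is undefined for matrices smaller than 4 cells")
    if not sort:
        return temperature_of(mb.values)
    return temperature_of(ntc_sort(mb).matrix.values)


# -- JDM ------------------------------------------------------------------


def _overlap_sums(lines: np.ndarray, opposite_size: int) -> tuple[float, float]:
    b = (lines != 0).astype(float)
    deg = b.sum(axis=1)
    shared = b @ b.T
    k, l = np.triu_indices(lines.shape[0], k=1)
    observed = float(shared[k, l].sum())
    expected = float((deg[k] * deg[l]).sum() / opposite_size)
    return observed, expected


def jdm(m: BipartiteMatrix) -> float:
    """Observed/expected neighbourhood overlap under the configuration model.

    For each side, the observed overlap of a pair of nodes (a, b) is
    |N(a) ∩ N(b)|; its configuration-model expectation is k_a * k_b / s
    with s the size of the opposite side.  The score sums both sides'
    observed overlaps and divides by the summed expectations.  Values
    above 1 indicate more shared partners than degree alone predicts
    (disassortative, nested structure).  Order-invariant.
    """
    _require_binary(m, "JDM")
    if m.n_rows < 2 and m.n_cols < 2:
        raise ValueError("JDM needs at least one side with two or more nodes")
    obs = exp = 0.0
    if m.n_rows >= 2:
        o, e = _overlap_sums(m.values, m.n_cols)
        obs, exp = obs + o, exp + e
    if m.n_cols >= 2:
        o, e = _overlap_sums(m.values.T, m.n_rows)
        obs, exp = obs + o, exp + e
    return obs / exp


# -- Discrepancy ----------------------------------------------------------


def discrepancy(m: BipartiteMatrix) -> int:
    """Presences that must move to reach the row-packed ideal (BR).

    With columns in their sorted order, row i's packed form holds its r_i
    presences in the leftmost r_i columns; the discrepancy counts the
    presences currently outside those positions, summed over rows.  Zero
    for a maximally packed matrix; lower is more nested.
    """
    _require_binary(m, "BR")
    b = m.values != 0
    r = b.sum(axis=1)
    inside = np.array([b[i, : r[i]].sum() for i in range(m.n_rows)])
    return int((r - inside).sum())


# -- Spectral radius ------------------------------------------------------


def spectral_radius(m: BipartiteMatrix) -> float:
    """Largest eigenvalue of the bipartite adjacency embedding [[0,B],[B^T,0]].

    Equals the largest singular value of the biadjacency matrix B;
    non-negative and invariant to row/column ordering.
    """
    return float(np.linalg.svd(m.values, compute_uv=False)[0])


# -- direction detection --------------------------------------------------


def direction_fixtures() -> tuple[BipartiteMatrix, BipartiteMatrix]:
    """Reference (nested, checkerboard) matrices used to orient measures.

    Both are weighted, have exactly 55 nonzero entries, and their entries
    sum to 220, so a measure's response separates structure from size:

    * nested: 10x10 with entry 12 - i - j wherever i + j <= 11 (1-based);
      a strictly decreasing weighted staircase.
    * checkerboard: 10x11 with entry 4 wherever i + j is even; the
      archetypal non-nested pattern.
    """
    i = np.arange(1, 11)[:, None]
    j = np.arange(1, 11)[None, :]
    nested = np.where(i + j <= 11, 12 - i - j, 0).astype(float)
    jj = np.arange(1, 12)[None, :]
    checker = np.where((i + jj) % 2 == 0, 4.0, 0.0)
    return BipartiteMatrix(nested), BipartiteMatrix(checker)


_MEASURE_FUNCS = {
    "NODF": nodf,
    "MD": manhattan_distance,
    "JDM": jdm,
    "BR": discrepancy,
    "WNODF": wnodf,
    "SR": spectral_radius,
}


def _score_one(measure_id: str, cfg: NestedConfiguration, sort: bool) -> float:
    """Score one measure given the degree-sorted configuration of a matrix."""
    if measure_id == "NTC":
        return temperature(cfg.matrix, sort=sort)
    func = _MEASURE_FUNCS[measure_id]
    mat = cfg.matrix
    if measure_id in BINARY_MEASURES:
        mat = mat.binarised()
    return float(func(mat))


@functools.lru_cache(maxsize=None)
def detect_direction(measure_id: str) -> Direction:
    """Which way the measure moves with increasing nestedness.

    Scores the two reference fixtures (binarised for binary-only measures)
    through the full sort-and-score pipeline and returns
    ``HIGHER_IS_MORE_NESTED`` iff the nested fixture outscores the
    checkerboard.  Memoized; equal scores on the fixtures mean the measure
    cannot be oriented and raise an error.
    """
    if measure_id not in ALL_MEASURES:
        raise ValueError(f"unknown measure {measure_id!r}; valid ids: {ALL_MEASURES}")
    nested, checker = direction_fixtures()
    scores = []
    for fixture in (nested, checker):
        cfg = degree_sort(fixture)
        scores.append(_score_one(measure_id, cfg, sort=True))
    if scores[0] == scores[1]:
        raise ValueError(f"cannot orient measure {measure_id}: fixtures score equally")
    return (
        Direction.HIGHER_IS_MORE_NESTED
        if scores[0] > scores[1]
        else Direction.LOWER_IS_MORE_NESTED
    )


def measure_score(m: BipartiteMatrix, measure_id: str, sort: bool = True) -> MeasureScore:
    """Score one measure on a stripped matrix, bundled with its direction."""
    value = score_matrix(m, (measure_id,), sort=sort)[measure_id]
    return MeasureScore(measure_id, value, detect_direction(measure_id))


def score_matrix(
    m: BipartiteMatrix, measures: tuple[str, ...] | list[str], sort: bool = True
) -> dict[str, float]:
    """Score a stripped matrix with several measures, sharing one sort.

    The degree-sorted arrangement (weight-aware on quantitative data) is
    computed once and reused by every order-sensitive measure; the
    temperature performs its own further minimisation from that start.
    With ``sort=False`` all measures see the matrix exactly as given,
    relaxing the context-free assumption.
    """
    cfg = degree_sort(m) if sort else identity_configuration(m)
    return {mid: _score_one(mid, cfg, sort) for mid in measures}
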