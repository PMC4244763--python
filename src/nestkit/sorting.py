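"""Maximally nested arrangements of a biadjacency matrix.

Order-sensitive nestedness scores (NODF, discrepancy, Manhattan distance,
temperature) are only meaningful once the matrix is put into a canonical
highly-nested arrangement; otherwise the score would depend on the
arbitrary ordering of rows and columns in the input file.  This module
produces that arrangement:

* :func:`degree_sort` — rows and columns by descending degree, with
  deterministic tie-breaking (weight-aware for quantitative data).
* :func:`ntc_sort` — a further deterministic hill-climb over adjacent
  row/column swaps that minimises the temperature, used only by the
  temperature measure.

Sorting permutes rows and columns independently; it never alters the
multiset of entries, the fill, or the degree sequences.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from ._ntc import temperature_of
from .core_io import BipartiteMatrix

__all__ = ["NestedConfiguration", "degree_sort", "ntc_sort", "identity_configuration"]


@dataclass(frozen=True)
class NestedConfiguration:
    """Row/column permutations realizing a nested arrangement.

    ``matrix`` is the permuted view; ``row_order[k]`` gives the original
    index of the row now in position k (same for columns).
    """

    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    matrix: BipartiteMatrix


def identity_configuration(m: BipartiteMatrix) -> NestedConfiguration:
    """The trivial arrangement: the matrix exactly as given."""
    return NestedConfiguration(tuple(range(m.n_rows)), tuple(range(m.n_cols)), m)


def _binary_line_order(lines: np.ndarray) -> list[int]:
    """Descending degree; ties by descending lexicographic 0/1 vector, then
    ascending original index."""
    degrees = np.count_nonzero(lines, axis=1)
    keys = [
        (-degrees[i], tuple(-x for x in (lines[i] != 0).astype(int)), i)
        for i in range(lines.shape[0])
    ]
    return sorted(range(lines.shape[0]), key=lambda i: keys[i])


def _weighted_line_order(lines: np.ndarray) -> list[int]:
    """Descending degree; ties broken by weight information.

    Between two lines of equal degree, the one holding greater values on
    the majority of mutually occupied positions ranks first; a remaining
    tie falls back to descending total sum, then ascending original index.
    """
    degrees = np.count_nonzero(lines, axis=1)
    sums = lines.sum(axis=1)

    def cmp(a: int, b: int) -> int:
        if degrees[a] != degrees[b]:
            return -1 if degrees[a] > degrees[b] else 1
        both = (lines[a] != 0) & (lines[b] != 0)
        a_wins = int(np.count_nonzero(lines[a][both] > lines[b][both]))
        b_wins = int(np.count_nonzero(lines[b][both] > lines[a][both]))
        if a_wins != b_wins:
            return -1 if a_wins > b_wins else 1
        if sums[a] != sums[b]:
            return -1 if sums[a] > sums[b] else 1
        return -1 if a < b else (1 if a > b else 0)

    return sorted(range(lines.shape[0]), key=functools.cmp_to_key(cmp))


def degree_sort(m: BipartiteMatrix, use_weights: bool | None = None) -> NestedConfiguration:
    """Arrange rows and columns by descending degree.

    ``use_weights`` selects the tie-breaking rules: weight-aware for
    quantitative matrices, lexicographic for binary ones.  Defaults to
    weight-aware iff the matrix is not binary.

    Columns are ordered first (line vectors read in the input row order),
    then rows against the new column order; the procedure is fully
    deterministic.
    """
    if use_weights is None:
        use_weights = not m.is_binary
    order_of = _weighted_line_order if use_weights else _binary_line_order
    col_order = order_of(m.values.T)
    row_order = order_of(m.values[:, col_order])
    return NestedConfiguration(tuple(row_order), tuple(col_order), m.permuted(row_order, col_order))


def _hill_climb_temperature(B: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Adjacent-swap descent on temperature; returns (row perm, col perm, T).

    A swap of two neighbouring rows (or columns) is accepted iff it
    strictly lowers the temperature; passes repeat until one full sweep
    over all adjacent pairs makes no change.  Deterministic.
    """
    n, m = B.shape
    rows = np.arange(n)
    cols = np.arange(m)
    work = B.copy()
    t = temperature_of(work)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            work[[i, i + 1]] = work[[i + 1, i]]
            t_new = temperature_of(work)
            if t_new < t:
                t = t_new
                rows[[i, i + 1]] = rows[[i + 1, i]]
                improved = True
            else:
                work[[i, i + 1]] = work[[i + 1, i]]
        for j in range(m - 1):
            work[:, [j, j + 1]] = work[:, [j + 1, j]]
            t_new = temperature_of(work)
            if t_new < t:
                t = t_new
                cols[[j, j + 1]] = cols[[j + 1, j]]
                improved = True
            else:
                work[:, [j, j + 1]] = work[:, [j + 1, j]]
    return rows, cols, t


def ntc_sort(m: BipartiteMatrix) -> NestedConfiguration:
    """Arrangement minimising the temperature, found deterministically.

    Starts from :func:`degree_sort` of the presence/absence pattern and
    hill-climbs over adjacent row-pair and column-pair swaps, accepting a
    swap only when the temperature strictly decreases, until a full pass
    changes nothing.  The result is never warmer than the degree-sorted
    arrangement.
    """
    mb = m.binarised()
    base = degree_sort(mb, use_weights=False)
    sub_rows, sub_cols, _ = _hill_climb_temperature(base.matrix.values)
    row_order = tuple(base.row_order[i] for i in sub_rows)
    col_order = tuple(base.col_order[j] for j in sub_cols)
    return NestedConfiguration(row_order, col_order, mb.permuted(row_order, col_order))
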