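"""Null models: randomized matrices conserving chosen features of the input.

Observed nestedness only becomes interpretable against an ensemble of
random matrices that share basic properties (shape, fill, degrees, totals)
with the input.  Five binary models and four weighted models are provided;
each conserves the features listed in its :class:`NullModelSpec`, exactly
where stated and only in expectation where stated.

Binary models
-------------
SS      fill cells placed uniformly at random (shape, fill exact)
FF      degree-preserving permutation via curveball trades
        (shape, fill, row and column degree sequences exact)
CC      fill cells sampled without replacement with inclusion weight
        (k_i/m + d_j/n)/2, biasing toward the observed degree structure
        (shape, fill exact; degrees in tendency only)
DD      independent Bernoulli cells with p_ij = (k_i/m + d_j/n)/2
        (degrees conserved in expectation)
EE      independent Bernoulli cells with p = F/(n*m)
        (fill conserved in expectation)

Weighted models (all keep the zero/nonzero pattern fixed)
---------------------------------------------------------
SHUFFLE the multiset of nonzero weights is permuted over the positions
CRT     per-row redistribution of weight; row totals exact
CCT     per-column mirror of CRT; column totals exact
RCTA    mean of an independent CRT and CCT draw; totals in expectation

DD, EE and CC can produce empty rows/columns; draws are returned as-is and
the ensemble pipeline strips them before sorting and measuring, so the
conservation contracts stay literal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core_io import BipartiteMatrix

__all__ = [
    "NullModelSpec",
    "NULL_MODELS",
    "BINARY_MODELS",
    "WEIGHTED_MODELS",
    "resolve_model_id",
    "generate_null_binary",
    "generate_null_weighted",
    "null_sampler",
    "CurveballSampler",
]


@dataclass(frozen=True)
class NullModelSpec:
    model_id: str
    input_class: str  # "binary" | "weighted"
    conserved: frozenset[str]
    description: str


NULL_MODELS: dict[str, NullModelSpec] = {
    s.model_id: s
    for s in [
        NullModelSpec("SS", "binary", frozenset({"shape", "fill"}), "shuffles positions randomly"),
        NullModelSpec(
            "FF",
            "binary",
            frozenset({"shape", "fill", "degree_sequence"}),
            "degree-preserving permutations of structure",
        ),
        NullModelSpec(
            "CC",
            "binary",
            frozenset({"shape", "fill"}),
            "degree-weighted placement; some structure preserved, rest shuffled",
        ),
        NullModelSpec(
            "DD",
            "binary",
            frozenset({"probabilistic_degree"}),
            "cells determined probabilistically by node degree",
        ),
        NullModelSpec(
            "EE",
            "binary",
            frozenset({"probabilistic_fill"}),
            "cells determined probabilistically by fill",
        ),
        NullModelSpec(
            "SHUFFLE",
            "weighted",
            frozenset({"binary_positions", "weight_multiset"}),
            "order of weighted links is swapped",
        ),
        NullModelSpec(
            "CRT",
            "weighted",
            frozenset({"binary_positions", "row_totals"}),
            "random weights conserving row totals",
        ),
        NullModelSpec(
            "CCT",
            "weighted",
            frozenset({"binary_positions", "col_totals"}),
            "random weights conserving column totals",
        ),
        NullModelSpec(
            "RCTA",
            "weighted",
            frozenset({"binary_positions"}),
            "average of row-total and column-total conserving draws",
        ),
    ]
}

BINARY_MODELS = ("SS", "FF", "CC", "DD", "EE")
WEIGHTED_MODELS = ("SHUFFLE", "CRT", "CCT", "RCTA")

#: numeric aliases for the binary models (1=SS, 2=CC, 3=FF, 4=DD, 5=EE)
_NUMERIC_ALIASES = {1: "SS", 2: "CC", 3: "FF", 4: "DD", 5: "EE"}


def resolve_model_id(model) -> str:
    """Accept a model id string or a numeric alias for the binary models."""
    if isinstance(model, int) or (isinstance(model, str) and model.isdigit()):
        k = int(model)
        if k not in _NUMERIC_ALIASES:
            raise ValueError(f"numeric null-model alias must be 1-5, got {k}")
        return _NUMERIC_ALIASES[k]
    mid = str(model).upper()
    if mid not in NULL_MODELS:
        raise ValueError(f"unknown null model {model!r}; valid ids: {sorted(NULL_MODELS)}")
    return mid


def _degree_weights(b: np.ndarray) -> np.ndarray:
    """Cell weights (k_i/m + d_j/n)/2 from row degrees k and column degrees d."""
    n, m = b.shape
    k = np.count_nonzero(b, axis=1)
    d = np.count_nonzero(b, axis=0)
    return (k[:, None] / m + d[None, :] / n) / 2.0


class CurveballSampler:
    """Degree-preserving sampler using curveball trades.

    A trade picks two rows and randomly reallocates the columns held by
    exactly one of them, preserving both rows' degrees and every column's
    degree.  Each draw applies ``trades_per_draw`` trades (default
    5*max(n, m)) to the current state and returns a copy, so successive
    draws chain along a single well-mixed Markov chain whose stationary
    distribution is uniform over matrices with the observed margins.
    """

    def __init__(self, m: BipartiteMatrix, rng: np.random.Generator, trades_per_draw: int | None = None):
        if m.n_rows < 2 or m.n_cols < 2:
            raise ValueError("FF needs at least 2 rows and 2 columns to trade")
        self._template = m
        self._state = (m.values != 0).astype(float)
        self._rng = rng
        self.trades_per_draw = trades_per_draw or 5 * max(m.shape)

    def _trade(self) -> None:
        n = self._state.shape[0]
        a, b = self._rng.choice(n, size=2, replace=False)
        ra, rb = self._state[a] != 0, self._state[b] != 0
        only_a = np.flatnonzero(ra & ~rb)
        only_b = np.flatnonzero(rb & ~ra)
        pool = np.concatenate([only_a, only_b])
        if pool.size == 0:
            return
        self._rng.shuffle(pool)
        new_a = pool[: only_a.size]
        new_b = pool[only_a.size :]
        self._state[a, only_a] = 0.0
        self._state[b, only_b] = 0.0
        self._state[a, new_a] = 1.0
        self._state[b, new_b] = 1.0

    def draw(self) -> BipartiteMatrix:
        for _ in range(self.trades_per_draw):
            self._trade()
        return BipartiteMatrix(self._state.copy(), self._template.row_labels, self._template.col_labels)


def _draw_ss(m: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    n, mm = m.shape
    out = np.zeros(n * mm)
    cells = rng.choice(n * mm, size=m.fill, replace=False)
    out[cells] = 1.0
    return BipartiteMatrix(out.reshape(n, mm), m.row_labels, m.col_labels)


def _draw_cc(m: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    n, mm = m.shape
    w = _degree_weights(m.values).ravel()
    cells = rng.choice(n * mm, size=m.fill, replace=False, p=w / w.sum())
    out = np.zeros(n * mm)
    out[cells] = 1.0
    return BipartiteMatrix(out.reshape(n, mm), m.row_labels, m.col_labels)


def _draw_dd(m: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    p = _degree_weights(m.values)
    out = (rng.random(m.shape) < p).astype(float)
    return BipartiteMatrix(out, m.row_labels, m.col_labels)


def _draw_ee(m: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    p = m.fill / (m.n_rows * m.n_cols)
    out = (rng.random(m.shape) < p).astype(float)
    return BipartiteMatrix(out, m.row_labels, m.col_labels)


def generate_null_binary(m: BipartiteMatrix, model, rng: np.random.Generator) -> BipartiteMatrix:
    """One draw from a binary null model (SS, FF, CC, DD or EE).

    FF burns in a fresh curveball chain from the observed matrix on every
    call; ensemble code should prefer :func:`null_sampler`, which chains
    FF draws for much better mixing per unit work.
    """
    mid = resolve_model_id(model)
    if mid not in BINARY_MODELS:
        raise ValueError(f"{mid} is not a binary null model")
    if not m.is_binary:
        raise ValueError("binary null models need a binary matrix; binarise first")
    if mid == "FF":
        return CurveballSampler(m, rng).draw()
    return {"SS": _draw_ss, "CC": _draw_cc, "DD": _draw_dd, "EE": _draw_ee}[mid](m, rng)


def _redistribute_rows(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """New positive weights on each row's occupied cells, row totals exact."""
    out = np.zeros_like(values)
    for i in range(values.shape[0]):
        occ = np.flatnonzero(values[i])
        c = occ.size
        if c == 0:  # empty line: nothing to redistribute
            continue
        total = values[i].sum()
        row = values[i, occ]
        if np.all(row == np.round(row)) and float(total).is_integer():
            # integer row: one unit per occupied cell, remainder multinomial
            alloc = np.ones(c) + rng.multinomial(int(total) - c, np.full(c, 1.0 / c))
        else:
            alloc = rng.dirichlet(np.ones(c)) * total
        out[i, occ] = alloc
    return out


def _draw_shuffle(m: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    out = np.zeros_like(m.values)
    pos = np.nonzero(m.values)
    out[pos] = rng.permutation(m.values[pos])
    return BipartiteMatrix(out, m.row_labels, m.col_labels)


def _draw_crt(m: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    return BipartiteMatrix(_redistribute_rows(m.values, rng), m.row_labels, m.col_labels)


def _draw_cct(m: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    return BipartiteMatrix(_redistribute_rows(m.values.T, rng).T, m.row_labels, m.col_labels)


def _draw_rcta(m: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    crt = _redistribute_rows(m.values, rng)
    cct = _redistribute_rows(m.values.T, rng).T
    return BipartiteMatrix((crt + cct) / 2.0, m.row_labels, m.col_labels)


def generate_null_weighted(m: BipartiteMatrix, model, rng: np.random.Generator) -> BipartiteMatrix:
    """One draw from a weighted null model (SHUFFLE, CRT, CCT or RCTA)."""
    mid = resolve_model_id(model)
    if mid not in WEIGHTED_MODELS:
        raise ValueError(f"{mid} is not a weighted null model")
    return {
        "SHUFFLE": _draw_shuffle,
        "CRT": _draw_crt,
        "CCT": _draw_cct,
        "RCTA": _draw_rcta,
    }[mid](m, rng)


def null_sampler(
    m: BipartiteMatrix, model, rng: np.random.Generator
) -> Callable[[], BipartiteMatrix]:
    """A zero-argument draw function for the given model, ready for loops.

    For FF this holds one chained curveball sampler so successive draws
    share a single Markov chain; all other models are memoryless.
    """
    mid = resolve_model_id(model)
    if mid == "FF":
        sampler = CurveballSampler(m, rng)
        return sampler.draw
    if mid in BINARY_MODELS:
        if not m.is_binary:
            raise ValueError("binary null models need a binary matrix; binarise first")
        func = {"SS": _draw_ss, "CC": _draw_cc, "DD": _draw_dd, "EE": _draw_ee}[mid]
    else:
        func = {"SHUFFLE": _draw_shuffle, "CRT": _draw_crt, "CCT": _draw_cct, "RCTA": _draw_rcta}[mid]
    return lambda: func(m, rng)
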