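"""Bipartite biadjacency matrices: the in-memory container and CSV/report I/O.

A bipartite network between two node classes (rows and columns) is held as a
dense non-negative matrix with unique string labels on both axes.  All other
modules consume and produce :class:`BipartiteMatrix` objects; labels travel
through every permutation so a reported nested configuration stays
interpretable in terms of the original node names.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BipartiteMatrix",
    "read_matrix",
    "write_matrix",
    "strip_empty",
    "write_report",
]


@dataclass(frozen=True)
class BipartiteMatrix:
    """Non-negative biadjacency matrix with row/column labels.

    Parameters
    ----------
    values
        ``(n_rows, n_cols)`` array of non-negative interaction weights.
        A matrix is *binary* iff every entry is 0 or 1.
    row_labels, col_labels
        Unique string labels, one per row/column.  Auto-generated
        (``R1..Rn`` / ``C1..Cm``) when omitted.
    """

    values: np.ndarray
    row_labels: tuple[str, ...] = field(default=())
    col_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("biadjacency matrix must be two-dimensional")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("matrix must have at least one row and one column")
        if not np.all(np.isfinite(arr)):
            raise ValueError("matrix entries must be finite")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative entry {arr[i, j]} at row {i + 1}, column {j + 1}; "
                "interaction weights must be non-negative"
            )
        object.__setattr__(self, "values", arr)
        rl = tuple(self.row_labels) or tuple(f"R{i + 1}" for i in range(arr.shape[0]))
        cl = tuple(self.col_labels) or tuple(f"C{j + 1}" for j in range(arr.shape[1]))
        if len(rl) != arr.shape[0]:
            raise ValueError("number of row labels does not match matrix rows")
        if len(cl) != arr.shape[1]:
            raise ValueError("number of column labels does not match matrix columns")
        if len(set(rl)) != len(rl):
            raise ValueError("row labels must be unique")
        if len(set(cl)) != len(cl):
            raise ValueError("column labels must be unique")
        object.__setattr__(self, "row_labels", rl)
        object.__setattr__(self, "col_labels", cl)

    # -- basic structural properties -------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def is_binary(self) -> bool:
        """True iff every entry is exactly 0 or 1."""
        v = self.values
        return bool(np.all((v == 0) | (v == 1)))

    @property
    def fill(self) -> int:
        """Number of nonzero entries."""
        return int(np.count_nonzero(self.values))

    def binary(self) -> np.ndarray:
        """0/1 presence pattern as a float array."""
        return (self.values != 0).astype(float)

    def binarised(self) -> "BipartiteMatrix":
        """Presence/absence version of this matrix (nonzero -> 1)."""
        if self.is_binary:
            return self
        return BipartiteMatrix(self.binary(), self.row_labels, self.col_labels)

    def permuted(self, row_order: Sequence[int], col_order: Sequence[int]) -> "BipartiteMatrix":
        """Return the matrix with rows/columns re-ordered, labels following."""
        ro = np.asarray(row_order)
        co = np.asarray(col_order)
        return BipartiteMatrix(
            self.values[np.ix_(ro, co)],
            tuple(self.row_labels[i] for i in ro),
            tuple(self.col_labels[j] for j in co),
        )


def _parse_cell(text: str, row: int, col: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"non-numeric entry {text!r} at row {row}, column {col}"
        ) from None


def read_matrix(path, has_headers: bool = True) -> BipartiteMatrix:
    """Read a biadjacency matrix from a comma-separated file.

    The dialect is fixed: comma separator, ``.`` decimal point.  When
    ``has_headers`` is true the first row holds column labels and the first
    column row labels (both together, never one alone); otherwise the whole
    file is numeric and labels are auto-generated.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: file contains no data")

    if has_headers:
        col_labels = tuple(c.strip() for c in rows[0][1:])
        body_rows = rows[1:]
        row_labels = tuple(r[0].strip() for r in body_rows)
        body = [r[1:] for r in body_rows]
    else:
        col_labels = ()
        row_labels = ()
        body = rows

    if not body:
        raise ValueError(f"{path}: no data rows")
    width = len(body[0])
    for i, r in enumerate(body):
        if len(r) != width:
            raise ValueError(
                f"{path}: ragged row {i + 1}: expected {width} fields, got {len(r)}"
            )
    values = np.array(
        [[_parse_cell(c, i + 1, j + 1) for j, c in enumerate(r)] for i, r in enumerate(body)]
    )
    return BipartiteMatrix(values, row_labels, col_labels)


def _format_value(x: float) -> str:
    """Render integers without a decimal point so binary CSVs round-trip."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_matrix(m: BipartiteMatrix, path, with_headers: bool = True) -> None:
    """Write a matrix back to CSV, optionally with its label headers."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if with_headers:
            w.writerow(["", *m.col_labels])
            for label, row in zip(m.row_labels, m.values):
                w.writerow([label, *(_format_value(x) for x in row)])
        else:
            for row in m.values:
                w.writerow([_format_value(x) for x in row])


def strip_empty(m: BipartiteMatrix) -> BipartiteMatrix:
    """Drop all-zero rows and columns, preserving the order of survivors.

    Idempotent.  Raises if every entry is zero (the network has no links).
    """
    keep_rows = np.flatnonzero(m.values.any(axis=1))
    keep_cols = np.flatnonzero(m.values.any(axis=0))
    if keep_rows.size == 0 or keep_cols.size == 0:
        raise ValueError("matrix has no nonzero entries; nothing to analyse")
    if keep_rows.size == m.n_rows and keep_cols.size == m.n_cols:
        return m
    return m.permuted(keep_rows, keep_cols)


# -- report output --------------------------------------------------------

_REPORT_FIELDS = [
    "null_model",
    "measure",
    "observed",
    "ensemble_size",
    "mean",
    "sd",
    "z_score",
    "p_value",
    "normalised_temperature",
]


def _render_p(p: float, p_is_bound: bool, n: int) -> str:
    if p_is_bound:
        return f"<{1 / n:g}"
    return f"{p:g}"


def _stats_record(s) -> dict:
    return {
        "null_model": s.model_id,
        "measure": s.measure_id,
        "observed": s.observed,
        "ensemble_size": s.N,
        "mean": s.mean,
        "sd": s.sd,
        "z_score": s.z,
        "p_value": _render_p(s.p, s.p_is_bound, s.N),
        "normalised_temperature": s.T,
    }


def write_report(stats, path, format: str = "json") -> None:
    """Write one record per (null model, measure) pair as JSON or TSV.

    A p-value that hit the ensemble resolution limit is rendered as
    ``"<1/N"`` (e.g. ``<0.001`` for N = 1000); the numeric 1/N stays in the
    record's structured fields only through the stats objects themselves.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("no statistics to report")
    records = [_stats_record(s) for s in stats]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_REPORT_FIELDS, delimiter="\t")
            w.writeheader()
            for rec in records:
                w.writerow(rec)
    else:
        raise ValueError(f"unknown report format {format!r}; use 'json' or 'tsv'")
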