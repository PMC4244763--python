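"""High-level model/results interface for a full nestedness significance test.

:class:`NestednessTest` bundles the whole pipeline — strip empty lines,
sort into the maximally nested arrangement, score the observed matrix,
build one null ensemble per selected null model, and summarize — behind a
fit() call returning a :class:`NestednessResults` with a printable summary
table, mirroring how regression packages expose Model.fit() -> Results.

    >>> test = NestednessTest.from_csv("network.csv", measures=("NODF", "SR"),
    ...                                null_models=("CC", "FF"))
    >>> res = test.fit(ensemble=1000, seed=42)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BipartiteMatrix, read_matrix, strip_empty, write_report
from .ensemble import ComparisonStats, EnsembleResult, compute_stats, run_adaptive_ensemble, run_fixed_ensemble
from .measures import (
    ALL_MEASURES,
    BINARY_MEASURES,
    detect_direction,
    score_matrix,
)
from .nulls import BINARY_MODELS, WEIGHTED_MODELS, resolve_model_id
from .sorting import NestedConfiguration, degree_sort, identity_configuration

__all__ = ["NestednessTest", "NestednessResults", "perform_nested_test"]


class NestednessTest:
    """A nestedness significance test bound to one input matrix.

    Parameters
    ----------
    matrix
        The biadjacency matrix (binary or weighted, not yet stripped).
    measures
        Measure ids among NODF, MD, NTC, JDM, BR, WNODF, SR.
    null_models
        Null-model ids (or numeric aliases 1-5 for the binary models).
    binary_mode
        Analyse presence/absence structure (True) or weights (False).
        Defaults to True for a binary matrix, False otherwise.  In binary
        mode a weighted matrix is binarised up front and WNODF is not
        available; in weighted mode binary-only measures are computed on
        the presence pattern of the (weighted) sorted arrangement.
    sort
        Sort rows/columns into the maximally nested arrangement before
        scoring (the context-free default).  False scores the matrix as
        given.
    """

    def __init__(
        self,
        matrix: BipartiteMatrix,
        measures=("NODF", "SR"),
        null_models=("CC", "FF"),
        binary_mode: bool | None = None,
        sort: bool = True,
    ):
        self.measures = tuple(str(m).upper() for m in measures)
        self.null_models = tuple(resolve_model_id(m) for m in null_models)
        if not self.measures:
            raise ValueError("select at least one measure")
        if not self.null_models:
            raise ValueError("select at least one null model")
        for mid in self.measures:
            if mid not in ALL_MEASURES:
                raise ValueError(f"unknown measure {mid!r}; valid ids: {ALL_MEASURES}")

        if binary_mode is None:
            binary_mode = matrix.is_binary
        self.binary_mode = bool(binary_mode)
        self.sort = bool(sort)

        if self.binary_mode:
            if "WNODF" in self.measures:
                raise ValueError("WNODF needs weighted analysis; drop it or set binary_mode=False")
            bad = [m for m in self.null_models if m not in BINARY_MODELS]
            if bad:
                raise ValueError(f"null models {bad} need weighted analysis (valid here: {BINARY_MODELS})")
            matrix = matrix.binarised()
        else:
            # weighted analysis of an all-ones binary matrix is degenerate but valid
            bad = [m for m in self.null_models if m not in WEIGHTED_MODELS]
            if bad:
                raise ValueError(f"null models {bad} need binary analysis (valid here: {WEIGHTED_MODELS})")
        self.matrix = matrix

    @classmethod
    def from_csv(cls, path, has_headers: bool = True, **kwargs) -> "NestednessTest":
        """Build a test from a CSV biadjacency matrix."""
        return cls(read_matrix(path, has_headers=has_headers), **kwargs)

    def fit(self, ensemble="adaptive", seed: int = 0, utest=None) -> "NestednessResults":
        """Run the full test.

        ensemble
            ``"adaptive"`` (default) for the self-sizing two-group scheme,
            or an integer N for a fixed-size ensemble.
        seed
            Master seed; each null model gets an independent substream
            derived from (seed, model index), so draws for one model do
            not shift when measures or other models are added.
        """
        stripped = strip_empty(self.matrix)
        config = degree_sort(stripped) if self.sort else identity_configuration(stripped)
        observed = score_matrix(stripped, self.measures, sort=self.sort)
        directions = {mid: detect_direction(mid) for mid in self.measures}

        ensembles: dict[str, EnsembleResult] = {}
        stats: list[ComparisonStats] = []
        for k, model in enumerate(self.null_models):
            rng = np.random.default_rng([int(seed), k])
            if ensemble == "adaptive":
                res = run_adaptive_ensemble(stripped, model, self.measures, rng, sort=self.sort, utest=utest)
            else:
                res = run_fixed_ensemble(stripped, model, self.measures, int(ensemble), rng, sort=self.sort)
            ensembles[model] = res
            for mid in self.measures:
                st = compute_stats(
                    observed[mid], res.scores[mid], directions[mid], measure_id=mid, model_id=model
                )
                stats.append(st)
        return NestednessResults(
            test=self,
            nested_configuration=config,
            observed=observed,
            directions=directions,
            ensembles=ensembles,
            stats=stats,
            seed=int(seed),
        )


@dataclass
class NestednessResults:
    """Fitted results: observed scores, null ensembles and comparison stats."""

    test: NestednessTest
    nested_configuration: NestedConfiguration
    observed: dict[str, float]
    directions: dict
    ensembles: dict[str, EnsembleResult]
    stats: list[ComparisonStats]
    seed: int

    def stats_for(self, model_id: str, measure_id: str) -> ComparisonStats:
        for s in self.stats:
            if s.model_id == model_id and s.measure_id == measure_id:
                return s
        raise KeyError(f"no statistics for model {model_id!r}, measure {measure_id!r}")

    def summary(self, float_fmt: str = "{:.4f}") -> str:
        """Plain-text summary table: one column per (null model, measure)."""

        def fmt(x):
            return "n/a" if x is None else float_fmt.format(x)

        cols = [(s.model_id, s.measure_id, s) for s in self.stats]
        rows = [
            ("Null model", [c[0] for c in cols]),
            ("Nestedness measure", [c[1] for c in cols]),
            ("Measure", [fmt(s.observed) for _, _, s in cols]),
            ("Ensemble Size", [str(s.N) for _, _, s in cols]),
            ("Mean", [fmt(s.mean) for _, _, s in cols]),
            ("Standard Deviation", [fmt(s.sd) for _, _, s in cols]),
            ("z-score", [fmt(s.z) for _, _, s in cols]),
            ("p-value", [f"<{1 / s.N:g}" if s.p_is_bound else f"{s.p:g}" for _, _, s in cols]),
            ("Normalised Temperature", [fmt(s.T) for _, _, s in cols]),
        ]
        label_w = max(len(r[0]) for r in rows)
        col_w = [max(len(r[1][i]) for r in rows) for i in range(len(cols))]
        lines = []
        for label, values in rows:
            cells = "  ".join(v.rjust(col_w[i]) for i, v in enumerate(values))
            lines.append(f"{label.ljust(label_w)}  {cells}")
        return "\n".join(lines)

    def to_records(self) -> list[dict]:
        """One plain dict per (null model, measure) pair, JSON-ready."""
        return [
            {
                "null_model": s.model_id,
                "measure": s.measure_id,
                "observed": s.observed,
                "ensemble_size": s.N,
                "mean": s.mean,
                "sd": s.sd,
                "z_score": s.z,
                "p_value": s.p,
                "p_is_bound": s.p_is_bound,
                "normalised_temperature": s.T,
                "direction": s.direction.value,
            }
            for s in self.stats
        ]

    def save_report(self, path, format: str = "json") -> None:
        write_report(self.stats, path, format=format)

    def save_ensemble_scores(self, path) -> None:
        """CSV of raw ensemble scores, one column per (model, measure)."""
        headers = []
        columns = []
        for model, res in self.ensembles.items():
            for mid, arr in res.scores.items():
                headers.append(f"{model}:{mid}")
                columns.append(arr)
        depth = max(len(c) for c in columns)
        with open(path, "w") as fh:
            fh.write(",".join(headers) + "\n")
            for i in range(depth):
                fh.write(",".join(repr(float(c[i])) if i < len(c) else "" for c in columns) + "\n")

    def plot_distributions(self, path) -> None:
        """Histograms of null scores with the observed score marked (PNG)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        pairs = [(s.model_id, s.measure_id, s) for s in self.stats]
        fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3), squeeze=False)
        for ax, (model, mid, s) in zip(axes[0], pairs):
            ax.hist(self.ensembles[model].scores[mid], bins=30, color="steelblue")
            ax.axvline(s.observed, color="crimson", linestyle="--")
            ax.set_title(f"{model} / {mid}")
            ax.set_xlabel(mid)
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)


def perform_nested_test(
    matrix: BipartiteMatrix,
    measures=("NODF", "SR"),
    null_models=("CC", "FF"),
    binary_mode: bool | None = None,
    sort: bool = True,
    ensemble="adaptive",
    seed: int = 0,
) -> NestednessResults:
    """One-call driver: build a :class:`NestednessTest` and fit it."""
    test = NestednessTest(
        matrix, measures=measures, null_models=null_models, binary_mode=binary_mode, sort=sort
    )
    return test.fit(ensemble=ensemble, seed=seed)
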