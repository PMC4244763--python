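"""Null ensembles and significance statistics.

Because the true null distribution of any nestedness score is unknown, the
package bootstraps it: it draws many matrices from a null model, pushes
each through exactly the same strip/sort/measure pipeline as the observed
matrix, and summarizes the observed score against the resulting score
arrays.  The ensemble size is either fixed by the caller or found
adaptively: two groups of scores grow in steps of 500 until a two-sample
Mann-Whitney U-test can no longer tell them apart at the 10% level, at
which point they merge (so the final N is at least 1,000 and a p-value as
small as 0.001 can always be resolved), with an unconditional merge at
100,000 members.

Per (null model, measure) pair the summary holds (writing <M> and sigma
for the ensemble mean and sample standard deviation of the score M):

* normalised temperature  T = M_observed / <M>
* sample z-score          z = (M_observed - <M>) / sigma
* p-value                 the frequency of ensemble members strictly more
  nested than the observed matrix, read in the measure's direction of
  increasing nestedness; when no member is more nested, p is reported as
  the resolution bound 1/N with ``p_is_bound`` set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core_io import BipartiteMatrix, strip_empty
from .measures import Direction, score_matrix
from .nulls import null_sampler, resolve_model_id

__all__ = [
    "EnsembleResult",
    "ComparisonStats",
    "run_fixed_ensemble",
    "run_adaptive_ensemble",
    "mann_whitney_u",
    "compute_stats",
    "normalised_temperature",
    "z_score",
]

MIN_GROUP = 500
GROWTH_STEP = 500
MAX_ENSEMBLE = 100_000
ADAPTIVE_ALPHA = 0.10
MAX_CONSECUTIVE_REDRAWS = 1_000


@dataclass
class EnsembleResult:
    """Scores of every selected measure over one null-model ensemble."""

    model_id: str
    scores: dict[str, np.ndarray]
    N: int
    adaptive: bool
    redraws: int = 0

    def __post_init__(self) -> None:
        for mid, arr in self.scores.items():
            if len(arr) != self.N:
                raise ValueError(f"score array for {mid} has length {len(arr)}, expected {self.N}")


@dataclass
class ComparisonStats:
    """Observed score versus one null ensemble for one measure."""

    measure_id: str
    model_id: str
    observed: float
    mean: float
    sd: float
    z: float | None
    T: float | None
    p: float
    p_is_bound: bool
    N: int
    direction: Direction = field(default=Direction.HIGHER_IS_MORE_NESTED)


def normalised_temperature(observed: float, mean: float) -> float | None:
    """T = observed / ensemble mean; None (with a warning) if the mean is 0."""
    if mean == 0:
        warnings.warn("ensemble mean is zero; normalised temperature undefined")
        return None
    return observed / mean

def z_score(observed: float, mean: float, sd: float) -> float | None:
    """z = (observed - mean) / sd; None (with a warning) if sd is 0."""
    if sd == 0:
        warnings.warn("ensemble standard deviation is zero; z-score undefined")
        return None
    return (observed - mean) / sd


def _score_draws(draw, measures, count: int, sort: bool):
    """Draw and score `count` null matrices; redraw on empty collapses."""
    out = {mid: [] for mid in measures}
    consecutive_failures = 0
    redraws = 0
    done = 0
    while done < count:
        candidate = draw()
        try:
            stripped = strip_empty(candidate)
        except ValueError:
            redraws += 1
            consecutive_failures += 1
            if consecutive_failures >= MAX_CONSECUTIVE_REDRAWS:
                raise RuntimeError(
                    f"{MAX_CONSECUTIVE_REDRAWS} consecutive null draws collapsed "
                    "to an empty matrix; the null model is degenerate for this input"
                )
            continue
        consecutive_failures = 0
        scores = score_matrix(stripped, measures, sort=sort)
        for mid in measures:
            out[mid].append(scores[mid])
        done += 1
    return out, redraws


def run_fixed_ensemble(
    m: BipartiteMatrix,
    model,
    measures,
    N: int,
    rng: np.random.Generator,
    sort: bool = True,
) -> EnsembleResult:
    """Ensemble of exactly N null draws, all measures scored on each draw.

    One shared set of draws serves every selected measure, so scores of
    different measures are directly comparable member by member.
    """
    if N < 1:
        raise ValueError("ensemble size must be at least 1")
    measures = tuple(measures)
    if not measures:
        raise ValueError("at least one measure is required")
    mid = resolve_model_id(model)
    draw = null_sampler(m, mid, rng)
    scored, redraws = _score_draws(draw, measures, N, sort)
    return EnsembleResult(
        mid, {k: np.asarray(v) for k, v in scored.items()}, N, adaptive=False, redraws=redraws
    )


def run_adaptive_ensemble(
    m: BipartiteMatrix,
    model,
    measures,
    rng: np.random.Generator,
    sort: bool = True,
    utest=None,
) -> EnsembleResult:
    """Grow two parallel ensembles until statistically indistinguishable.

    Both groups start at 500 members and grow by 500 each per round; after
    every round a Mann-Whitney U-test compares the two groups' scores of
    the first selected measure.  When that test cannot reject identity of
    the two groups at the 10% level, the groups merge into the final
    ensemble (N >= 1,000).  If rejection persists, the merge is forced
    when the combined size reaches 100,000.  ``utest`` may override the
    two-sample test (used to exercise the cap).
    """
    measures = tuple(measures)
    if not measures:
        raise ValueError("at least one measure is required")
    mid = resolve_model_id(model)
    test = utest if utest is not None else mann_whitney_u
    draw = null_sampler(m, mid, rng)
    lead = measures[0]

    redraws = 0
    groups = []
    for _ in range(2):
        scored, r = _score_draws(draw, measures, MIN_GROUP, sort)
        groups.append(scored)
        redraws += r

    while True:
        combined = len(groups[0][lead]) + len(groups[1][lead])
        p = test(np.asarray(groups[0][lead]), np.asarray(groups[1][lead]))
        if p > ADAPTIVE_ALPHA or combined >= MAX_ENSEMBLE:
            break
        for g in groups:
            scored, r = _score_draws(draw, measures, GROWTH_STEP, sort)
            redraws += r
            for k in measures:
                g[k].extend(scored[k])

    merged = {
        k: np.asarray(groups[0][k] + groups[1][k]) for k in measures
    }
    return EnsembleResult(mid, merged, len(merged[lead]), adaptive=True, redraws=redraws)


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann-Whitney U-test p-value for two independent samples.

    Uses the normal approximation with tie and continuity corrections at
    the group sizes the adaptive ensemble produces (>= 500); tiny
    tie-free samples are evaluated exactly.  Identical constant samples
    give p = 1 (the test has nothing to distinguish).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    method = "exact" if (x.size <= 20 and y.size <= 20 and np.unique(pooled).size == pooled.size) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compute_stats(
    observed: float,
    ensemble: np.ndarray,
    direction: Direction,
    measure_id: str = "",
    model_id: str = "",
) -> ComparisonStats:
    """Summarize an observed score against one ensemble of null scores.

    The p-value counts ensemble members strictly more nested than the
    observed matrix (strictly greater scores when the measure increases
    with nestedness, strictly smaller otherwise); ties count as not more
    nested.  With zero such members p is conservatively reported as the
    bound 1/N.  The standard deviation uses the N-1 denominator.
    """
    arr = np.asarray(ensemble, dtype=float)
    N = arr.size
    if N < 1:
        raise ValueError("ensemble must contain at least one score")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if N > 1 else 0.0
    if direction is Direction.HIGHER_IS_MORE_NESTED:
        c = int(np.count_nonzero(arr > observed))
    else:
        c = int(np.count_nonzero(arr < observed))
    if c > 0:
        p, bound = c / N, False
    else:
        p, bound = 1.0 / N, True
    return ComparisonStats(
        measure_id=measure_id,
        model_id=model_id,
        observed=float(observed),
        mean=mean,
        sd=sd,
        z=z_score(observed, mean, sd),
        T=normalised_temperature(observed, mean),
        p=p,
        p_is_bound=bound,
        N=N,
        direction=direction,
    )
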