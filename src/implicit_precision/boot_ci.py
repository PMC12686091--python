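"""Per-participant bootstrap: replicates, basic intervals, difference CIs.

Each participant's own trial-level data is the distribution resampled: a
replicate re-scores a with-replacement resample of their trials. The
default interval is the basic (reverse-percentile) interval

    (2*theta_hat - Q_{1-alpha/2},  2*theta_hat - Q_{alpha/2})

built from the empirical quantiles Q of the replicate distribution.
Bounds are deliberately not clipped to the metric's range: the basic
method can legally produce PI bounds outside [0, 1], and preserving them
keeps interval widths honest. Percentile and BCa intervals are available
for comparison.

Resampling is stratified by condition role by default, preserving n_A and
n_B in every replicate (an unstratified resample can empty a pool, which
no score survives). Scoring is vectorized across replicates for the four
built-in metrics; an arbitrary callable falls back to a Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import scoring
from .scoring import DegenerateDataError, ScoreSpec

__all__ = [
    "BootstrapSpec",
    "IntervalEstimate",
    "ReplicateSet",
    "replicate_scores",
    "basic_interval",
    "percentile_interval",
    "bca_interval",
    "interval_from_replicates",
    "bootstrap_participant_ci",
    "pairwise_difference_ci",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BootstrapSpec:
    n_resamples: int = 2000
    method: Literal["basic", "percentile", "bca"] = "basic"
    alpha: float = 0.05
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class IntervalEstimate:
    estimate: float
    lower: float
    upper: float
    method: str
    n_resamples: int

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError("interval lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class ReplicateSet:
    """Cached bootstrap replicates for one participant's score."""

    participant_id: str
    replicates: np.ndarray
    estimate: float
    n_dropped: int = 0


_MATRIX_SCORERS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "PI": scoring.pi_score_matrix,
    "D": scoring.d_score_matrix,
    "prop_diff": scoring.mean_diff_matrix,
    "latency_diff": scoring.mean_diff_matrix,
}


def _resample_matrix(
    values: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    return values[idx]


def replicate_scores(
    values_a: np.ndarray,
    values_b: np.ndarray,
    score_spec: ScoreSpec,
    boot: BootstrapSpec,
    *,
    participant_id: str = "",
    score_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> ReplicateSet:
    """Bootstrap-replicate one participant's score.

    Stratified resampling draws n_A values from pool A and n_B from pool B
    per replicate; unstratified resampling draws from the pooled trials and
    redraws any replicate that empties a pool (at most 100 times, then the
    replicate is dropped with a count in ``n_dropped``). Replicates whose
    score is undefined (zero pooled SD for D) are likewise redrawn.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if score_spec.orientation == "A-minus-B":
        a, b = b, a
    if score_fn is None:
        estimate = _MATRIX_SCORERS[score_spec.metric](a[None, :], b[None, :])[0]
        if np.isnan(estimate):
            raise DegenerateDataError("score undefined on the observed data")
    else:
        estimate = float(score_fn(a, b))

    rng = np.random.default_rng(boot.seed)
    n = boot.n_resamples

    def score_block(m_a: np.ndarray, m_b: np.ndarray) -> np.ndarray:
        if score_fn is None:
            return _MATRIX_SCORERS[score_spec.metric](m_a, m_b)
        return np.array([score_fn(ra, rb) for ra, rb in zip(m_a, m_b)])

    if boot.stratified:
        reps = score_block(_resample_matrix(a, n, rng), _resample_matrix(b, n, rng))
        n_dropped = 0
        for _ in range(_MAX_REDRAWS):
            bad = np.isnan(reps)
            if not bad.any():
                break
            k = int(bad.sum())
            reps[bad] = score_block(
                _resample_matrix(a, k, rng), _resample_matrix(b, k, rng)
            )
        bad = np.isnan(reps)
        n_dropped = int(bad.sum())
        reps = reps[~bad]
    else:
        pooled = np.concatenate([a, b])
        n_a = a.size
        reps_list: list[float] = []
        n_dropped = 0
        while len(reps_list) < n:
            need = n - len(reps_list)
            idx = rng.integers(0, pooled.size, size=(need, pooled.size))
            for row in idx:
                ra, rb = pooled[row[:n_a]], pooled[row[n_a:]]
                val = score_block(ra[None, :], rb[None, :])[0]
                if np.isnan(val):
                    n_dropped += 1
                    if n_dropped > _MAX_REDRAWS:
                        n = len(reps_list)  # give up on the remainder
                        break
                    continue
                reps_list.append(float(val))
            else:
                continue
            break
        reps = np.asarray(reps_list)

    if reps.size == 0:
        raise DegenerateDataError(
            "no valid bootstrap replicate could be drawn (all-constant data?)"
        )
    return ReplicateSet(
        participant_id=participant_id,
        replicates=reps,
        estimate=float(estimate),
        n_dropped=n_dropped,
    )


def _quantiles(replicates: np.ndarray, alpha: float) -> tuple[float, float]:
    # linear (type-7) interpolation, numpy's default: fixed for reproducibility
    lo, hi = np.quantile(replicates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def basic_interval(
    estimate: float, replicates: np.ndarray, alpha: float = 0.05
) -> IntervalEstimate:
    """Basic (reverse-percentile) interval: (2θ̂ − Q_hi, 2θ̂ − Q_lo)."""
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size == 0:
        raise ValueError("replicates must be non-empty")
    q_lo, q_hi = _quantiles(replicates, alpha)
    return IntervalEstimate(
        estimate=float(estimate),
        lower=2.0 * estimate - q_hi,
        upper=2.0 * estimate - q_lo,
        method="basic",
        n_resamples=int(replicates.size),
    )


def percentile_interval(
    estimate: float, replicates: np.ndarray, alpha: float = 0.05
) -> IntervalEstimate:
    replicates = np.asarray(replicates, dtype=float)
    q_lo, q_hi = _quantiles(replicates, alpha)
    return IntervalEstimate(
        estimate=float(estimate),
        lower=q_lo,
        upper=q_hi,
        method="percentile",
        n_resamples=int(replicates.size),
    )


def bca_interval(
    estimate: float,
    replicates: np.ndarray,
    alpha: float = 0.05,
    *,
    acceleration: float = 0.0,
) -> IntervalEstimate:
    """Bias-corrected (and optionally accelerated) percentile interval.

    Provided for comparison only; with ``acceleration=0`` this is the BC
    interval. The jackknife acceleration constant is the caller's business
    because replicate sets are cached without the raw trials.
    """
    replicates = np.asarray(replicates, dtype=float)
    prop_below = np.mean(replicates < estimate) + 0.5 * np.mean(replicates == estimate)
    prop_below = min(max(prop_below, 1.0 / (replicates.size + 1)), 1.0 - 1.0 / (replicates.size + 1))
    z0 = norm.ppf(prop_below)
    z = norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = norm.cdf(z0 + (z0 + z) / (1.0 - acceleration * (z0 + z)))
    q_lo, q_hi = np.quantile(replicates, adj)
    return IntervalEstimate(
        estimate=float(estimate),
        lower=float(q_lo),
        upper=float(q_hi),
        method="bca",
        n_resamples=int(replicates.size),
    )


def interval_from_replicates(
    estimate: float, replicates: np.ndarray, spec: BootstrapSpec
) -> IntervalEstimate:
    if spec.method == "basic":
        return basic_interval(estimate, replicates, spec.alpha)
    if spec.method == "percentile":
        return percentile_interval(estimate, replicates, spec.alpha)
    return bca_interval(estimate, replicates, spec.alpha)


def bootstrap_participant_ci(
    values_a: np.ndarray,
    values_b: np.ndarray,
    score_spec: ScoreSpec,
    boot: BootstrapSpec,
    *,
    participant_id: str = "",
) -> tuple[IntervalEstimate, ReplicateSet]:
    """Replicate one participant's score and build their interval."""
    reps = replicate_scores(
        values_a, values_b, score_spec, boot, participant_id=participant_id
    )
    return interval_from_replicates(reps.estimate, reps.replicates, boot), reps


def pairwise_difference_ci(
    rep_i: ReplicateSet, rep_j: ReplicateSet, alpha: float = 0.05
) -> IntervalEstimate:
    """Basic interval on the score difference of two participants.

    Pairs the two cached replicate streams index by index (statistically
    fine for independent participants) rather than re-bootstrapping the
    pair from raw trials. Downstream, "discriminable" means this interval
    excludes zero.
    """
    if rep_i.replicates.size != rep_j.replicates.size:
        raise ValueError("replicate sets must have equal length to be paired")
    diffs = rep_i.replicates - rep_j.replicates
    return basic_interval(rep_i.estimate - rep_j.estimate, diffs, alpha)
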