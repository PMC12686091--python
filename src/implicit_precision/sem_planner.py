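"""Standard error of measurement and individual-precision planning.

The classical route to an individual's confidence interval runs through
the standard error of measurement, SEm = SD * sqrt(1 - r), with SD the
score standard deviation and r the test-retest reliability; the 95%
interval on a score is then score +/- 1.96 * SEm. These utilities
complement the bootstrap route with that algebra, plus two planning
tools: the maximal symmetric CI width that still separates two labelled
score cut-offs, and a simulator of false-positive / false-negative rates
when comparing two individuals' noisy scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CutoffScheme",
    "PROJECT_IMPLICIT_CUTOFFS",
    "ErrorRateSimSpec",
    "sem",
    "sem_interval",
    "required_ci_width",
    "simulate_error_rates",
    "comparison_power",
    "dscore_cutoff_intervals",
]


@dataclass(frozen=True)
class CutoffScheme:
    """Labelled, strictly increasing score cut-offs."""

    cutoffs: dict[str, float] = field(
        default_factory=lambda: {
            "no bias": 0.0,
            "weak": 0.15,
            "moderate": 0.35,
            "strong": 0.65,
        }
    )

    def __post_init__(self) -> None:
        values = list(self.cutoffs.values())
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("cut-offs must be strictly increasing")

    @property
    def values(self) -> list[float]:
        return list(self.cutoffs.values())

    def adjacent_pairs(self) -> list[tuple[str, str, float, float]]:
        items = list(self.cutoffs.items())
        return [
            (a_label, b_label, a, b)
            for (a_label, a), (b_label, b) in zip(items, items[1:])
        ]


#: The feedback cut-offs historically used for the IAT D score
#: (0 / 0.15 / 0.35 / 0.65 for no / weak / moderate / strong bias).
PROJECT_IMPLICIT_CUTOFFS = CutoffScheme()


@dataclass(frozen=True)
class ErrorRateSimSpec:
    true_difference: float
    measurement_sd: float
    alpha: float = 0.05
    n_sims: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_sd < 0:
            raise ValueError("measurement_sd must be >= 0")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def sem(sd: float, r: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - r)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0.0 <= r <= 1.0:
        raise ValueError("reliability must lie in [0, 1]")
    return sd * sqrt(1.0 - r)


def sem_interval(
    score: float, sem_value: float, z: float = 1.96
) -> tuple[float, float]:
    """Symmetric individual-score interval: score +/- z * SEm."""
    if sem_value < 0:
        raise ValueError("sem_value must be >= 0")
    half = z * sem_value
    return score - half, score + half


def required_ci_width(cutoff_low: float, cutoff_high: float) -> float:
    """Maximal symmetric CI width that separates two score cut-offs.

    A score at one cut-off has a symmetric interval excluding the other
    exactly when the half-width is below the cut-off gap, i.e. when the
    full width is below ``2 * (cutoff_high - cutoff_low)``.
    """
    if cutoff_high <= cutoff_low:
        raise ValueError("cutoff_high must exceed cutoff_low")
    return 2.0 * (cutoff_high - cutoff_low)


def comparison_power(true_difference: float, measurement_sd: float, alpha: float = 0.05) -> float:
    """Closed-form probability of declaring two noisy scores different.

    The observed difference of two independent scores with error SD sigma
    is Normal(true_difference, 2 sigma^2); a difference is declared when
    |observed| > z * sqrt(2) * sigma.
    """
    if measurement_sd == 0.0:
        return 1.0 if true_difference != 0.0 else 0.0
    z = norm.ppf(1.0 - alpha / 2.0)
    shift = abs(true_difference) / (sqrt(2.0) * measurement_sd)
    return float(norm.sf(z - shift) + norm.cdf(-z - shift))


def simulate_error_rates(spec: ErrorRateSimSpec) -> tuple[float, float]:
    """Monte-Carlo error rates for comparing two individuals' scores.

    Draws ``n_sims`` pairs of observed scores — true scores differing by
    ``true_difference`` plus independent Normal(0, measurement_sd^2)
    errors — and declares a difference when the observed gap exceeds
    ``z * sqrt(2) * measurement_sd`` (the two-score error inflation).
    Returns ``(false_positive_rate, false_negative_rate)``: the FPR is the
    declaration rate under a zero true difference, the FNR the miss rate
    under the specified one.
    """
    rng = np.random.default_rng(spec.seed)
    z = norm.ppf(1.0 - spec.alpha / 2.0)
    crit = z * sqrt(2.0) * spec.measurement_sd

    def declare_rate(true_diff: float) -> float:
        obs_1 = rng.normal(0.0, spec.measurement_sd, spec.n_sims)
        obs_2 = rng.normal(true_diff, spec.measurement_sd, spec.n_sims)
        if spec.measurement_sd == 0.0:
            return float(np.mean(np.abs(obs_2 - obs_1) > 0.0))
        return float(np.mean(np.abs(obs_2 - obs_1) > crit))

    fpr = declare_rate(0.0)
    fnr = 1.0 - declare_rate(spec.true_difference)
    return fpr, fnr


def dscore_cutoff_intervals(
    intervals: pd.DataFrame,
    scheme: CutoffScheme = PROJECT_IMPLICIT_CUTOFFS,
    tolerance: float = 0.02,
    *,
    summary: str = "median",
) -> pd.DataFrame:
    """Typical bootstrap CI at each labelled cut-off of a score scale.

    For each cut-off, takes the participants whose point estimate lies
    within ``+/- tolerance`` of it and summarizes their interval bounds
    (median by default, mean optionally). Cut-offs with an empty
    neighborhood produce a row flagged ``missing=True``. ``intervals``
    needs columns ``estimate``, ``lower``, ``upper``.
    """
    agg = {"median": np.median, "mean": np.mean}[summary]
    rows = []
    for label, cutoff in scheme.cutoffs.items():
        near = intervals[(intervals["estimate"] - cutoff).abs() <= tolerance]
        if near.empty:
            rows.append(
                {
                    "label": label,
                    "cutoff": cutoff,
                    "lower": np.nan,
                    "upper": np.nan,
                    "n_participants": 0,
                    "missing": True,
                }
            )
        else:
            rows.append(
                {
                    "label": label,
                    "cutoff": cutoff,
                    "lower": float(agg(near["lower"])),
                    "upper": float(agg(near["upper"])),
                    "n_participants": int(len(near)),
                    "missing": False,
                }
            )
    return pd.DataFrame(rows)
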