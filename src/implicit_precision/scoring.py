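"""Per-participant point estimates: probabilistic index and native scores.

The primary metric is the probabilistic index (PI; also known as the
common-language effect size or Ruscio's A): the probability that a randomly
selected response from condition pool B is larger than one from pool A,
ties counted half. It equals the Mann-Whitney U statistic divided by
``n_A * n_B`` and lies in [0, 1] with 0.5 as the point of zero effect.
Because it is rank-based, the same score applies to latency tasks and to
binary evaluative tasks alike, which is what makes different task paradigms
comparable on one scale.

Native scores are provided for comparison: the IAT-family D score (mean
latency difference over the inclusive SD of all critical-trial latencies),
the evaluative proportion difference, and the raw mean latency difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .trial_data import KEY_COLUMNS

__all__ = [
    "Metric",
    "ScoreSpec",
    "InsufficientDataError",
    "DegenerateDataError",
    "pi_score",
    "pi_score_matrix",
    "d_score",
    "d_score_matrix",
    "native_score",
    "mean_diff_matrix",
    "score_participants",
]

Metric = Literal["PI", "D", "prop_diff", "latency_diff"]


class InsufficientDataError(ValueError):
    """Too few trials in a role to compute the requested score."""


class DegenerateDataError(ValueError):
    """Score undefined on this data (e.g., zero pooled SD for D)."""


@dataclass(frozen=True)
class ScoreSpec:
    """How to turn one participant's critical trials into a point estimate.

    ``orientation="B-over-A"`` (default) makes larger-than-0.5 PI and
    positive D both read as "pool B responses larger", so the two metrics
    agree in sign; ``"A-minus-B"`` flips both. Error trials are retained by
    default since rank-based scoring has no error-penalty step.
    """

    metric: Metric = "PI"
    orientation: Literal["B-over-A", "A-minus-B"] = "B-over-A"
    d_variant: Literal["all-trials-inclusive-SD"] = "all-trials-inclusive-SD"
    min_trials_per_role: int = 2
    include_error_trials: bool = True

    def __post_init__(self) -> None:
        if self.metric not in ("PI", "D", "prop_diff", "latency_diff"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.min_trials_per_role < 2:
            raise ValueError("min_trials_per_role must be >= 2")

    @property
    def value_column(self) -> str:
        return "response_value" if self.metric in ("PI", "prop_diff") else "latency_ms"

    @property
    def null_value(self) -> float:
        """The metric's point of zero effect."""
        return 0.5 if self.metric == "PI" else 0.0


def pi_score(values_a: Iterable[float], values_b: Iterable[float]) -> float:
    """Probability that a random B response exceeds a random A response.

    Ties count half. Computed via midranks in O(n log n); equals
    ``(#{b > a} + 0.5 * #{b == a}) / (n_A * n_B)``.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both condition pools must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[a.size :].sum() - b.size * (b.size + 1) / 2.0
    return float(u / (a.size * b.size))


def pi_score_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise PI for resample matrices ``a`` (m, n_A) and ``b`` (m, n_B)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    n_a, n_b = a.shape[1], b.shape[1]
    ranks = rankdata(np.concatenate([a, b], axis=1), axis=1)
    u = ranks[:, n_a:].sum(axis=1) - n_b * (n_b + 1) / 2.0
    return u / (n_a * n_b)


def _inclusive_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1))


def d_score(
    latencies_a: Iterable[float],
    latencies_b: Iterable[float],
) -> float:
    """IAT-family D: (mean B - mean A) / inclusive SD of all critical trials.

    The inclusive SD pools both roles' latencies (n - 1 denominator).
    """
    a = np.asarray(list(latencies_a), dtype=float)
    b = np.asarray(list(latencies_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("D needs at least 2 trials per role")
    sd = _inclusive_sd(np.concatenate([a, b]))
    if sd == 0.0:
        raise DegenerateDataError("zero pooled SD: all latencies identical")
    return float((b.mean() - a.mean()) / sd)


def d_score_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise D for resample matrices; rows with zero pooled SD yield NaN."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    sd = np.std(np.concatenate([a, b], axis=1), axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (b.mean(axis=1) - a.mean(axis=1)) / sd
    d[sd == 0.0] = np.nan
    return d


def mean_diff_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise mean(B) - mean(A) (proportion or latency difference)."""
    return np.atleast_2d(b).mean(axis=1) - np.atleast_2d(a).mean(axis=1)


def native_score(
    values_a: Iterable[float],
    values_b: Iterable[float],
    metric: Metric,
) -> float:
    """Mean-difference native scores: ``prop_diff`` or ``latency_diff``."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both condition pools must be non-empty")
    if metric not in ("prop_diff", "latency_diff"):
        raise ValueError(f"native_score handles prop_diff/latency_diff, not {metric}")
    return float(b.mean() - a.mean())


def score_one(values_a: np.ndarray, values_b: np.ndarray, spec: ScoreSpec) -> float:
    """Score a single participant's two pools under ``spec``."""
    if min(values_a.size, values_b.size) < spec.min_trials_per_role:
        raise InsufficientDataError(
            f"fewer than {spec.min_trials_per_role} trials in a role"
        )
    if spec.orientation == "A-minus-B":
        values_a, values_b = values_b, values_a
    if spec.metric == "PI":
        return pi_score(values_a, values_b)
    if spec.metric == "D":
        return d_score(values_a, values_b)
    return native_score(values_a, values_b, spec.metric)


def participant_pools(
    trials: pd.DataFrame, spec: ScoreSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the two value pools for one participant's critical trials."""
    t = trials
    if not spec.include_error_trials and "accuracy" in t.columns:
        acc = t["accuracy"]
        t = t[acc.isna() | (acc == 1)]
    col = spec.value_column
    a = t.loc[t["block_role"] == "A", col].dropna().to_numpy(dtype=float)
    b = t.loc[t["block_role"] == "B", col].dropna().to_numpy(dtype=float)
    return a, b


def score_participants(trials: pd.DataFrame, spec: ScoreSpec) -> pd.DataFrame:
    """Score every participant x measure x domain cell in a trial table.

    Returns one row per cell with columns ``participant_id, measure, domain,
    metric, estimate, n_A, n_B``. Cells failing the scoring preconditions
    (a missing role, too few trials, degenerate data) are skipped and listed
    in the frame's ``.attrs["skipped"]``.
    """
    rows = []
    skipped = []
    for key, group in trials.groupby(KEY_COLUMNS, sort=False):
        a, b = participant_pools(group, spec)
        try:
            est = score_one(a, b, spec)
        except (InsufficientDataError, DegenerateDataError) as err:
            skipped.append({**dict(zip(KEY_COLUMNS, key)), "reason": str(err)})
            continue
        rows.append(
            {
                **dict(zip(KEY_COLUMNS, key)),
                "metric": spec.metric,
                "estimate": est,
                "n_A": int(a.size),
                "n_B": int(b.size),
            }
        )
    out = pd.DataFrame(
        rows, columns=KEY_COLUMNS + ["metric", "estimate", "n_A", "n_B"]
    )
    out.attrs["skipped"] = skipped
    return out
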