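"""Synthetic trial-level data with known ground truth.

Emulates the structure of six implicit-measure paradigms — IAT, Brief IAT,
Single-Target IAT, AMP, GNAT, EPT — closely enough to exercise every
downstream stage with a known answer key, and no more. Each simulated
participant has a latent condition shift ``delta_i ~ Normal(mu_delta,
tau_delta^2)``. Latency tasks draw role-A latencies from an ex-Gaussian
(Gaussian plus exponential tail, the standard minimal reaction-time model)
and role-B latencies from the same distribution shifted by ``delta_i``;
binary evaluative tasks draw Bernoulli responses with the shift applied on
the logit scale. The ground-truth table records each participant's latent
shift and its implied true probabilistic index ``pi_true``, the quantity
the pipeline's interval estimates are later checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .trial_data import TRIAL_COLUMNS

__all__ = [
    "TaskTemplate",
    "PopulationSpec",
    "DEFAULT_TEMPLATES",
    "DEFAULT_ROLE_MAP",
    "true_pi_normal_shift",
    "true_pi_bernoulli",
    "true_pi_exgaussian_shift",
    "delta_for_pi",
    "simulate_cohort",
    "simulate_task_data",
    "simulate_study",
]


@dataclass(frozen=True)
class TaskTemplate:
    """Trial budget and noise model of one task paradigm.

    ``latency_exp_tail_ms`` is the mean of the exponential component of the
    ex-Gaussian; set against ``latency_sd_ms`` it controls skew. For binary
    tasks ``binary_base_p`` is the role-A response probability and the
    participant shift acts on the logit scale.
    """

    measure: str
    response_kind: str  # "latency" | "binary"
    n_trials_A: int
    n_trials_B: int
    latency_base_ms: float = 600.0
    latency_sd_ms: float = 100.0
    latency_exp_tail_ms: float = 150.0
    error_rate: float = 0.08
    binary_base_p: float = 0.5

    def __post_init__(self) -> None:
        if self.response_kind not in ("latency", "binary"):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")
        if min(self.n_trials_A, self.n_trials_B) < 2:
            raise ValueError("trial counts must be >= 2")
        if min(self.latency_base_ms, self.latency_sd_ms, self.latency_exp_tail_ms) <= 0:
            raise ValueError("latency parameters must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class PopulationSpec:
    """Population of latent condition shifts.

    ``mu_delta`` / ``tau_delta`` are in milliseconds for latency tasks and
    on the logit scale for binary tasks.
    """

    n_participants: int
    mu_delta: float
    tau_delta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.tau_delta < 0:
            raise ValueError("tau_delta must be >= 0")


#: Trial budgets mirror the relative budgets of the six paradigms: the IAT
#: has the largest critical-trial count per condition, its brief variant the
#: smallest, and the evaluative-priming-style tasks sit in between.
DEFAULT_TEMPLATES: dict[str, TaskTemplate] = {
    "IAT": TaskTemplate("IAT", "latency", 60, 60),
    "BIAT": TaskTemplate("BIAT", "latency", 20, 20),
    "STIAT": TaskTemplate("STIAT", "latency", 38, 38),
    "AMP": TaskTemplate("AMP", "binary", 36, 36, binary_base_p=0.5),
    "GNAT": TaskTemplate("GNAT", "latency", 32, 32),
    "EPT": TaskTemplate("EPT", "latency", 24, 24),
}

#: Block labels emitted by the generator, mapped back to roles.
DEFAULT_ROLE_MAP: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    m: (("critical_A",), ("critical_B",)) for m in DEFAULT_TEMPLATES
}


def true_pi_normal_shift(delta: float, sigma: float) -> float:
    """PI implied by an additive shift under equal-variance Gaussian noise.

    The probability that a draw from ``Normal(m + delta, sigma^2)`` exceeds
    an independent draw from ``Normal(m, sigma^2)``: ``Phi(delta / (sigma *
    sqrt(2)))``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(norm.cdf(delta / (sigma * np.sqrt(2.0))))


def true_pi_bernoulli(p_a: float, p_b: float) -> float:
    """PI for binary responses: P(B > A) plus half the tie probability."""
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p_b * (1.0 - p_a) + 0.5 * (p_a * p_b + (1.0 - p_a) * (1.0 - p_b)))


_EXG_CACHE: dict[tuple[float, float, int, int], np.ndarray] = {}


def true_pi_exgaussian_shift(
    deltas: np.ndarray | float,
    sigma: float,
    tail: float,
    *,
    n_pairs: int = 1_000_000,
    seed: int = 987_654_321,
) -> np.ndarray:
    """PI implied by an additive shift under ex-Gaussian noise.

    No convenient closed form exists, so the distribution of the difference
    of two independent ex-Gaussian draws is evaluated once by a fixed-seed
    Monte Carlo of ``n_pairs`` pairs (sorted and cached per noise setting);
    each requested shift is then a ``searchsorted`` lookup, accurate to
    roughly 1/sqrt(n_pairs).
    """
    if sigma <= 0 or tail <= 0:
        raise ValueError("sigma and tail must be positive")
    key = (float(sigma), float(tail), int(n_pairs), int(seed))
    diffs = _EXG_CACHE.get(key)
    if diffs is None:
        rng = np.random.default_rng(seed)
        x1 = rng.normal(0.0, sigma, n_pairs) + rng.exponential(tail, n_pairs)
        x2 = rng.normal(0.0, sigma, n_pairs) + rng.exponential(tail, n_pairs)
        diffs = np.sort(x2 - x1)
        _EXG_CACHE[key] = diffs
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    # P(X2 + delta > X1) = P(X2 - X1 > -delta); diffs distribution is symmetric
    pi = np.searchsorted(diffs, deltas, side="left") / n_pairs
    return pi


def delta_for_pi(
    pi: np.ndarray | float,
    sigma: float,
    tail: float,
    *,
    n_pairs: int = 1_000_000,
    seed: int = 987_654_321,
) -> np.ndarray:
    """Latency shift whose implied PI equals ``pi`` under ex-Gaussian noise.

    Inverts :func:`true_pi_exgaussian_shift` through the same cached
    difference sample, so ``true_pi_exgaussian_shift(delta_for_pi(p)) == p``
    up to Monte-Carlo resolution.
    """
    true_pi_exgaussian_shift(0.0, sigma, tail, n_pairs=n_pairs, seed=seed)
    diffs = _EXG_CACHE[(float(sigma), float(tail), int(n_pairs), int(seed))]
    pi = np.atleast_1d(np.asarray(pi, dtype=float))
    if np.any((pi <= 0.0) | (pi >= 1.0)):
        raise ValueError("target PI must lie strictly inside (0, 1)")
    return np.quantile(diffs, pi)


def simulate_cohort(
    deltas: np.ndarray,
    template: TaskTemplate,
    *,
    domain: str = "synthetic",
    id_prefix: str = "P",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a latency-task cohort with caller-chosen participant shifts.

    Like :func:`simulate_task_data` but with the latent shifts supplied
    directly instead of drawn from a population — the handle used by
    calibration studies that need participants at exact true-PI values.
    """
    if template.response_kind != "latency":
        raise ValueError("simulate_cohort handles latency templates")
    deltas = np.asarray(deltas, dtype=float)
    pop = PopulationSpec(n_participants=deltas.size, mu_delta=0.0, tau_delta=0.0, seed=seed)
    pi_true = true_pi_exgaussian_shift(
        deltas, template.latency_sd_ms, template.latency_exp_tail_ms
    )
    ids = [f"{id_prefix}{i + 1:04d}" for i in range(deltas.size)]
    n_a, n_b = template.n_trials_A, template.n_trials_B
    rows = []
    for i, pid in enumerate(ids):
        rng = _participant_rng(pop.seed, template.measure, domain, pid)
        lat_a = rng.normal(template.latency_base_ms, template.latency_sd_ms, n_a)
        lat_a += rng.exponential(template.latency_exp_tail_ms, n_a)
        lat_b = rng.normal(
            template.latency_base_ms + deltas[i], template.latency_sd_ms, n_b
        )
        lat_b += rng.exponential(template.latency_exp_tail_ms, n_b)
        lat = np.maximum(np.concatenate([lat_a, lat_b]), 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "measure": template.measure,
                    "domain": domain,
                    "block_label": ["critical_A"] * n_a + ["critical_B"] * n_b,
                    "block_role": ["A"] * n_a + ["B"] * n_b,
                    "trial_index": np.arange(1, n_a + n_b + 1),
                    "latency_ms": lat,
                    "accuracy": (
                        rng.random(n_a + n_b) >= template.error_rate
                    ).astype(float),
                    "response_value": lat,
                }
            )
        )
    trials = pd.concat(rows, ignore_index=True)[TRIAL_COLUMNS]
    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "measure": template.measure,
            "domain": domain,
            "delta_true": deltas,
            "pi_true": pi_true,
        }
    )
    return trials, truth


def _participant_rng(seed: int, measure: str, domain: str, pid: str) -> np.random.Generator:
    """Per-participant stream, stable under reordering of participants."""
    import hashlib

    digest = hashlib.sha256(f"{measure}\x1f{domain}\x1f{pid}".encode()).digest()
    sub = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def simulate_task_data(
    template: TaskTemplate,
    pop: PopulationSpec,
    *,
    domain: str = "synthetic",
    id_prefix: str = "P",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one measure x domain cell.

    Returns ``(trials, ground_truth)``: a canonical trial table plus one
    ground-truth row per participant with ``delta_true`` and ``pi_true``.
    Reproducible: identical inputs give identical outputs. Latencies are
    floored at 1 ms (the floor is essentially never hit at the default
    noise scales).
    """
    delta_rng = np.random.default_rng(
        np.random.SeedSequence([pop.seed, hash_stable(f"{template.measure}\x1f{domain}")])
    )
    ids = [f"{id_prefix}{i + 1:04d}" for i in range(pop.n_participants)]
    deltas = delta_rng.normal(pop.mu_delta, pop.tau_delta, pop.n_participants)

    n_a, n_b = template.n_trials_A, template.n_trials_B
    trial_rows: list[pd.DataFrame] = []
    if template.response_kind == "latency":
        pi_true = true_pi_exgaussian_shift(
            deltas, template.latency_sd_ms, template.latency_exp_tail_ms
        )
    else:
        p_a = template.binary_base_p
        p_b = expit(logit(p_a) + deltas)
        pi_true = np.array([true_pi_bernoulli(p_a, pb) for pb in p_b])

    for i, pid in enumerate(ids):
        rng = _participant_rng(pop.seed, template.measure, domain, pid)
        if template.response_kind == "latency":
            lat_a = rng.normal(template.latency_base_ms, template.latency_sd_ms, n_a)
            lat_a += rng.exponential(template.latency_exp_tail_ms, n_a)
            lat_b = rng.normal(
                template.latency_base_ms + deltas[i], template.latency_sd_ms, n_b
            )
            lat_b += rng.exponential(template.latency_exp_tail_ms, n_b)
            lat = np.maximum(np.concatenate([lat_a, lat_b]), 1.0)
            acc = (rng.random(n_a + n_b) >= template.error_rate).astype(float)
            resp = lat.copy()
        else:
            p_b = float(expit(logit(template.binary_base_p) + deltas[i]))
            resp_a = (rng.random(n_a) < template.binary_base_p).astype(float)
            resp_b = (rng.random(n_b) < p_b).astype(float)
            resp = np.concatenate([resp_a, resp_b])
            # evaluative tasks still log a response latency; no correct answer
            lat = np.maximum(
                rng.normal(template.latency_base_ms, template.latency_sd_ms, n_a + n_b)
                + rng.exponential(template.latency_exp_tail_ms, n_a + n_b),
                1.0,
            )
            acc = np.full(n_a + n_b, np.nan)
        trial_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "measure": template.measure,
                    "domain": domain,
                    "block_label": ["critical_A"] * n_a + ["critical_B"] * n_b,
                    "block_role": ["A"] * n_a + ["B"] * n_b,
                    "trial_index": np.arange(1, n_a + n_b + 1),
                    "latency_ms": lat,
                    "accuracy": acc,
                    "response_value": resp,
                }
            )
        )
    trials = pd.concat(trial_rows, ignore_index=True)[TRIAL_COLUMNS]
    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "measure": template.measure,
            "domain": domain,
            "delta_true": deltas,
            "pi_true": pi_true,
        }
    )
    return trials, truth


def hash_stable(text: str) -> int:
    """64-bit stable hash of a string (for seed derivation)."""
    import hashlib

    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "little")


def simulate_study(
    *,
    n_participants: int = 50,
    domains: tuple[str, ...] = ("politics", "race", "self"),
    templates: Mapping[str, TaskTemplate] = DEFAULT_TEMPLATES,
    mu_delta_latency: float = 80.0,
    tau_delta_latency: float = 60.0,
    mu_delta_logit: float = 0.8,
    tau_delta_logit: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full measures x domains study with shared population settings.

    Default latency shifts (mean 80 ms, between-person SD 60 ms, against
    ex-Gaussian noise with SD 100 ms plus a 150 ms exponential tail) put the
    typical true PI near 0.6 with realistic person-to-person spread; the
    logit-scale analogue does the same for binary tasks. Each cell draws an
    independent participant sample, mirroring random assignment of
    task/domain combinations to visitors.
    """
    all_trials, all_truth = [], []
    for measure, template in templates.items():
        latency = template.response_kind == "latency"
        for domain in domains:
            pop = PopulationSpec(
                n_participants=n_participants,
                mu_delta=mu_delta_latency if latency else mu_delta_logit,
                tau_delta=tau_delta_latency if latency else tau_delta_logit,
                seed=seed,
            )
            prefix = f"{measure}-{domain}-P"
            trials, truth = simulate_task_data(
                template, pop, domain=domain, id_prefix=prefix
            )
            all_trials.append(trials)
            all_truth.append(truth)
    return (
        pd.concat(all_trials, ignore_index=True),
        pd.concat(all_truth, ignore_index=True),
    )
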