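"""Trial-level data model: reading, condition-role assignment, exclusions.

The single currency of the pipeline is a long-format *trial table*: a
:class:`pandas.DataFrame` with one row per trial and the columns in
:data:`TRIAL_COLUMNS`. Every participant contributes trials to exactly two
score-defining condition pools, labelled role ``"A"`` and role ``"B"``
(e.g., the compatible and incompatible critical blocks of an IAT). Scores
downstream compare the response distributions of the two pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "KEY_COLUMNS",
    "SchemaError",
    "ConfigurationError",
    "ExclusionPolicy",
    "ExclusionReport",
    "read_trials",
    "write_trials",
    "validate_trials",
    "assign_condition_roles",
    "apply_exclusions",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = [
    "participant_id",
    "measure",
    "domain",
    "block_label",
    "block_role",
    "trial_index",
    "latency_ms",
    "accuracy",
    "response_value",
]

#: Columns identifying a scoring cell member.
KEY_COLUMNS = ["participant_id", "measure", "domain"]

_REQUIRED_INPUT = [
    "participant_id",
    "measure",
    "domain",
    "block_label",
    "trial_index",
    "latency_ms",
]


class SchemaError(ValueError):
    """A required column is missing or the file is unusable."""


class ConfigurationError(ValueError):
    """A role map or policy is internally inconsistent."""


@dataclass(frozen=True)
class ExclusionPolicy:
    """Performance-based trial and participant exclusion rules.

    Defaults follow common practice for latency tasks: retain trials in
    [300 ms, 10 000 ms]; drop participants with more than 10% of trials
    faster than 300 ms, accuracy below 0.80 (computed over non-missing
    accuracy only, so evaluative tasks without a correct answer are
    unaffected), or fewer than 2 trials in either condition pool. All
    thresholds are configurable; they are working assumptions, not claims
    about any particular study's criteria.
    """

    min_latency_ms: float = 300.0
    max_latency_ms: float = 10_000.0
    fast_trial_threshold_ms: float = 300.0
    max_fast_trial_proportion: float = 0.10
    min_accuracy_proportion: float = 0.80
    min_trials_per_role: int = 2

    def __post_init__(self) -> None:
        if not self.min_latency_ms < self.max_latency_ms:
            raise ConfigurationError(
                "min_latency_ms must be below max_latency_ms"
            )
        for name in ("max_fast_trial_proportion", "min_accuracy_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.min_trials_per_role < 2:
            raise ConfigurationError("min_trials_per_role must be >= 2")

    @classmethod
    def identity(cls) -> "ExclusionPolicy":
        """A policy that removes nothing (infinite window, zero thresholds)."""
        return cls(
            min_latency_ms=0.0,
            max_latency_ms=math.inf,
            fast_trial_threshold_ms=0.0,
            max_fast_trial_proportion=1.0,
            min_accuracy_proportion=0.0,
            min_trials_per_role=2,
        )


@dataclass
class ExclusionReport:
    """Bookkeeping for one :func:`apply_exclusions` pass."""

    n_trials_in: int = 0
    n_trials_retained: int = 0
    n_trials_removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_participants_in: int = 0
    n_participants_retained: int = 0
    n_participants_removed_by_rule: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": "trial", "rule": "input", "count": self.n_trials_in},
            {"level": "trial", "rule": "retained", "count": self.n_trials_retained},
        ]
        rows += [
            {"level": "trial", "rule": rule, "count": n}
            for rule, n in self.n_trials_removed_by_rule.items()
        ]
        rows += [
            {"level": "participant", "rule": "input", "count": self.n_participants_in},
            {
                "level": "participant",
                "rule": "retained",
                "count": self.n_participants_retained,
            },
        ]
        rows += [
            {"level": "participant", "rule": rule, "count": n}
            for rule, n in self.n_participants_removed_by_rule.items()
        ]
        return pd.DataFrame(rows, columns=["level", "rule", "count"])


def read_trials(
    path: str | Path,
    schema_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a long-format trial CSV into a canonical trial table.

    Parameters
    ----------
    path
        CSV file with a header row, one row per trial.
    schema_map
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"latency_ms": "rt"}``. Unmapped canonical names are
        looked up verbatim.

    Unparseable latency / accuracy / response values become missing (NaN);
    row order is preserved. Missing required columns raise
    :class:`SchemaError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    if raw.empty:
        raise SchemaError(f"{path} contains no trial rows")
    schema_map = dict(schema_map or {})
    rename = {}
    for canonical in TRIAL_COLUMNS:
        source = schema_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
    df = raw.rename(columns=rename)
    for col in _REQUIRED_INPUT:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {path.name}")
    for col in ("block_role", "accuracy", "response_value"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[TRIAL_COLUMNS].copy()
    df["trial_index"] = pd.to_numeric(df["trial_index"], errors="coerce").astype("Int64")
    for col in ("latency_ms", "accuracy", "response_value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df.reset_index(drop=True)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as UTF-8 CSV in canonical column order."""
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def validate_trials(trials: pd.DataFrame, *, require_roles: bool = False) -> None:
    """Raise if the table violates the trial-table invariants.

    Checks positive latencies, unique (participant, measure, domain,
    trial_index) keys, and — when ``require_roles`` — that block_role is
    one of {"A", "B"} everywhere and both roles are present for every
    participant cell.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table lacks columns: {missing}")
    lat = trials["latency_ms"].to_numpy(dtype=float)
    if np.any(~np.isnan(lat) & (lat <= 0)):
        raise ValueError("latency_ms must be positive for every trial")
    keys = trials[KEY_COLUMNS + ["trial_index"]]
    if keys.duplicated().any():
        raise ValueError(
            "(participant_id, measure, domain, trial_index) must be unique"
        )
    if require_roles:
        roles = trials["block_role"]
        if not roles.isin(["A", "B"]).all():
            raise ValueError("block_role must be 'A' or 'B' for every trial")
        per_cell = trials.groupby(KEY_COLUMNS, sort=False)["block_role"].nunique()
        incomplete = per_cell[per_cell < 2]
        if len(incomplete):
            raise ValueError(
                f"{len(incomplete)} participant cell(s) lack one of the two roles"
            )


RoleMap = Mapping[str, tuple[Sequence[str], Sequence[str]]]


def assign_condition_roles(trials: pd.DataFrame, role_map: RoleMap) -> pd.DataFrame:
    """Assign each trial to condition pool A or B from its block label.

    ``role_map`` maps a measure name to a pair of block-label collections
    ``(labels_A, labels_B)``. Trials whose label appears in neither set are
    treated as non-critical (practice) trials and dropped. A measure present
    in the data but absent from the map, an empty label set, or a label in
    both sets raises :class:`ConfigurationError`.
    """
    present = trials["measure"].unique()
    for measure in present:
        if measure not in role_map:
            raise ConfigurationError(f"no role mapping for measure {measure!r}")
        labels_a, labels_b = role_map[measure]
        set_a, set_b = set(map(str, labels_a)), set(map(str, labels_b))
        if not set_a or not set_b:
            raise ConfigurationError(
                f"role mapping for measure {measure!r} has an empty label set"
            )
        overlap = set_a & set_b
        if overlap:
            raise ConfigurationError(
                f"labels {sorted(overlap)} mapped to both roles for {measure!r}"
            )

    out = trials.copy()
    role = pd.Series(pd.NA, index=out.index, dtype="object")
    labels = out["block_label"].astype(str)
    for measure in present:
        labels_a, labels_b = role_map[measure]
        in_measure = out["measure"] == measure
        role[in_measure & labels.isin(set(map(str, labels_a)))] = "A"
        role[in_measure & labels.isin(set(map(str, labels_b)))] = "B"
    out["block_role"] = role
    return out[role.notna()].reset_index(drop=True)


def apply_exclusions(
    trials: pd.DataFrame, policy: ExclusionPolicy
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply trial- then participant-level performance exclusions.

    Trial rule: latencies outside ``[min_latency_ms, max_latency_ms]`` are
    removed. Participant rules (evaluated per participant x measure x domain
    cell on the pre-window data for the fast-trial rate, post-window for
    counts): too many fast trials, low accuracy (non-missing subset only),
    or fewer than ``min_trials_per_role`` trials in either role. A removed
    participant cell loses all of its trials. Counts reconcile exactly:
    ``n_trials_in == n_trials_retained + sum(removed-by-rule)``.
    """
    report = ExclusionReport(
        n_trials_in=len(trials),
        n_participants_in=trials.groupby(KEY_COLUMNS, sort=False).ngroups,
    )
    lat = trials["latency_ms"].to_numpy(dtype=float)
    in_window = (lat >= policy.min_latency_ms) & (lat <= policy.max_latency_ms)
    report.n_trials_removed_by_rule["latency_window"] = int((~in_window).sum())

    fast = lat < policy.fast_trial_threshold_ms
    cell_of = trials[KEY_COLUMNS].astype(str).agg("\x1f".join, axis=1)
    fast_prop = pd.Series(fast).groupby(cell_of, sort=False).mean()

    kept = trials[in_window]
    kept_cells = cell_of[in_window]
    removed_cells: dict[str, str] = {}

    for cell, prop in fast_prop.items():
        if prop > policy.max_fast_trial_proportion:
            removed_cells[cell] = "fast_trials"
    if len(kept):
        acc = kept.groupby(kept_cells, sort=False)["accuracy"].mean()
        for cell, mean_acc in acc.items():
            if cell in removed_cells:
                continue
            if not np.isnan(mean_acc) and mean_acc < policy.min_accuracy_proportion:
                removed_cells[cell] = "low_accuracy"
        role_counts = kept.groupby([kept_cells, kept["block_role"]], sort=False).size()
        for cell in kept_cells.unique():
            if cell in removed_cells:
                continue
            n_a = int(role_counts.get((cell, "A"), 0))
            n_b = int(role_counts.get((cell, "B"), 0))
            if min(n_a, n_b) < policy.min_trials_per_role:
                removed_cells[cell] = "too_few_trials_per_role"
    # cells absent from kept (all trials outside the window) have no role trials
    for cell in set(cell_of.unique()) - set(kept_cells.unique()):
        removed_cells.setdefault(cell, "too_few_trials_per_role")

    drop_mask = kept_cells.isin(removed_cells)
    out = kept[~drop_mask.to_numpy()].reset_index(drop=True)

    by_rule: dict[str, int] = {}
    trial_loss: dict[str, int] = {}
    lost = kept_cells[drop_mask.to_numpy()]
    for cell, rule in removed_cells.items():
        by_rule[rule] = by_rule.get(rule, 0) + 1
        trial_loss[rule] = trial_loss.get(rule, 0) + int((lost == cell).sum())
    report.n_participants_removed_by_rule = by_rule
    for rule, n in trial_loss.items():
        report.n_trials_removed_by_rule[f"participant_{rule}"] = n
    report.n_trials_retained = len(out)
    report.n_participants_retained = (
        out.groupby(KEY_COLUMNS, sort=False).ngroups if len(out) else 0
    )
    return out, report
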