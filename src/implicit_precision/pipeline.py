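"""End-to-end orchestration of a precision study.

``run_precision_study`` wires the stages together — trial data (or the
synthetic generator) -> exclusions -> scoring -> per-participant bootstrap
-> the three precision statistics -> the weighted meta-model — and returns
a :class:`ReportBundle` of tidy tables plus a run manifest. Everything is
deterministic under the config's global seed: per-participant bootstrap
seeds are derived from the seed and the participant's identity, so results
do not depend on row order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boot_ci import (
    BootstrapSpec,
    IntervalEstimate,
    ReplicateSet,
    interval_from_replicates,
    replicate_scores,
)
from .meta_model import (
    MetaDataset,
    fit_weighted_lmm,
    estimated_marginal_means,
    pairwise_contrasts,
)
from .precision_metrics import (
    cell_proportion_detectable,
    discriminability_cell_rows,
    coverage_proportion,
    detectable_from_zero,
    map_width,
    offset_proportion,
    offset_variance,
)
from .scoring import (
    DegenerateDataError,
    InsufficientDataError,
    ScoreSpec,
    participant_pools,
)
from .synthetic_data import hash_stable, simulate_study
from .trial_data import KEY_COLUMNS, ExclusionPolicy, apply_exclusions

log = logging.getLogger("implicit_precision")

__all__ = ["StudyConfig", "ReportBundle", "StageError", "run_precision_study",
           "summarize_report", "write_bundle"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending cell."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one study run."""

    n_participants: int = 50
    domains: tuple[str, ...] = ("politics", "race", "self")
    score_spec: ScoreSpec = field(default_factory=ScoreSpec)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    exclusion_policy: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    apply_exclusion_policy: bool = True
    alpha: float = 0.05
    run_rqs: tuple[int, ...] = (1, 2, 3)
    seed: int = 0
    rq2_max_per_cell: int | None = None  # optional seeded subsample cap

    def digest(self) -> str:
        payload = json.dumps(
            {
                "n_participants": self.n_participants,
                "domains": list(self.domains),
                "score_spec": asdict(self.score_spec),
                "bootstrap": asdict(self.bootstrap),
                "exclusion_policy": asdict(self.exclusion_policy),
                "apply_exclusion_policy": self.apply_exclusion_policy,
                "alpha": self.alpha,
                "run_rqs": list(self.run_rqs),
                "seed": self.seed,
                "rq2_max_per_cell": self.rq2_max_per_cell,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Tidy tables of one study run (the machine-readable report)."""

    scores: pd.DataFrame
    intervals: pd.DataFrame
    participant_precision: pd.DataFrame
    cell_summaries: pd.DataFrame
    map_widths: pd.DataFrame
    meta_emms: pd.DataFrame
    meta_contrasts: pd.DataFrame
    exclusion_report: pd.DataFrame
    ground_truth: pd.DataFrame | None
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "scores": self.scores,
            "intervals": self.intervals,
            "participant_precision": self.participant_precision,
            "cell_summaries": self.cell_summaries,
            "map_widths": self.map_widths,
            "meta_emms": self.meta_emms,
            "meta_contrasts": self.meta_contrasts,
            "exclusion_report": self.exclusion_report,
        }
        if self.ground_truth is not None:
            out["ground_truth"] = self.ground_truth
        return out


def _participant_boot_seed(global_seed: int, key: tuple) -> int:
    # stable under participant reordering; independent across cells
    return int(
        np.random.SeedSequence(
            [global_seed, hash_stable("\x1f".join(map(str, key)))]
        ).generate_state(1)[0]
    )


def bootstrap_cells(
    trials: pd.DataFrame,
    score_spec: ScoreSpec,
    boot: BootstrapSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple, list[ReplicateSet]]]:
    """Score and bootstrap every participant cell of a trial table.

    Returns (scores, intervals, replicates-by-cell). Participants whose
    data cannot be scored are skipped and logged, mirroring
    ``score_participants``.
    """
    score_rows, interval_rows = [], []
    reps_by_cell: dict[tuple, list[ReplicateSet]] = {}
    for key, group in trials.groupby(KEY_COLUMNS, sort=False):
        pid, measure, domain = key
        a, b = participant_pools(group, score_spec)
        if min(a.size, b.size) < score_spec.min_trials_per_role:
            log.info("skipping %s (%s/%s): too few trials", pid, measure, domain)
            continue
        seed = _participant_boot_seed(boot.seed, key + (score_spec.metric,))
        pboot = BootstrapSpec(
            n_resamples=boot.n_resamples,
            method=boot.method,
            alpha=boot.alpha,
            seed=seed,
            stratified=boot.stratified,
        )
        try:
            reps = replicate_scores(a, b, score_spec, pboot, participant_id=pid)
        except (InsufficientDataError, DegenerateDataError) as err:
            log.info("skipping %s (%s/%s): %s", pid, measure, domain, err)
            continue
        interval = interval_from_replicates(reps.estimate, reps.replicates, pboot)
        score_rows.append(
            {
                "participant_id": pid,
                "measure": measure,
                "domain": domain,
                "metric": score_spec.metric,
                "estimate": reps.estimate,
                "n_A": int(a.size),
                "n_B": int(b.size),
            }
        )
        interval_rows.append(
            {
                "participant_id": pid,
                "measure": measure,
                "domain": domain,
                "metric": score_spec.metric,
                "estimate": interval.estimate,
                "lower": interval.lower,
                "upper": interval.upper,
                "width": interval.width,
                "method": interval.method,
                "n_resamples": interval.n_resamples,
            }
        )
        reps_by_cell.setdefault((measure, domain), []).append(reps)
    scores = pd.DataFrame(
        score_rows,
        columns=KEY_COLUMNS + ["metric", "estimate", "n_A", "n_B"],
    )
    intervals = pd.DataFrame(
        interval_rows,
        columns=KEY_COLUMNS
        + ["metric", "estimate", "lower", "upper", "width", "method", "n_resamples"],
    )
    return scores, intervals, reps_by_cell


def run_precision_study(
    config: StudyConfig,
    trials: pd.DataFrame | None = None,
    ground_truth: pd.DataFrame | None = None,
) -> ReportBundle:
    """Run the full pipeline; synthetic data are generated when none given."""
    if trials is None:
        trials, ground_truth = simulate_study(
            n_participants=config.n_participants,
            domains=config.domains,
            seed=config.seed,
        )
    if config.apply_exclusion_policy:
        trials, excl = apply_exclusions(trials, config.exclusion_policy)
    else:
        trials, excl = apply_exclusions(trials, ExclusionPolicy.identity())
    if trials.empty:
        raise StageError("exclusions", "no trials survive the exclusion policy")

    scores, intervals, reps_by_cell = bootstrap_cells(
        trials, config.score_spec, config.bootstrap
    )
    if scores.empty:
        raise StageError("scoring", "no participant could be scored")

    null_value = config.score_spec.null_value
    cell_rows, precision_rows, map_rows = [], [], []
    for (measure, domain), reps in sorted(reps_by_cell.items()):
        cell_iv = intervals[
            (intervals["measure"] == measure) & (intervals["domain"] == domain)
        ]
        ivs = [
            IntervalEstimate(
                estimate=r.estimate,
                lower=r.lower,
                upper=r.upper,
                method=r.method,
                n_resamples=r.n_resamples,
            )
            for r in cell_iv.itertuples()
        ]
        map_rows.append(
            {
                "measure": measure,
                "domain": domain,
                "map_ci_width": map_width(cell_iv["width"].to_numpy()),
                "n_participants": len(ivs),
            }
        )
        det_flags = [detectable_from_zero(iv, null_value) for iv in ivs]
        if 1 in config.run_rqs:
            cs = cell_proportion_detectable(det_flags, measure=measure, domain=domain)
            cell_rows.append(
                {
                    "measure": measure,
                    "domain": domain,
                    "statistic": cs.statistic,
                    "proportion": cs.proportion,
                    "variance": cs.variance,
                    "n_units": cs.n_units,
                }
            )
        disc_by_pid: dict[str, dict] = {}
        if 2 in config.run_rqs:
            if len(reps) < 2:
                raise StageError(
                    "RQ2",
                    f"cell {measure}/{domain} has {len(reps)} participant(s); "
                    "discriminability needs at least 2",
                )
            use = reps
            if (
                config.rq2_max_per_cell is not None
                and len(reps) > config.rq2_max_per_cell
            ):
                rng = np.random.default_rng(
                    _participant_boot_seed(config.seed, (measure, domain, "rq2"))
                )
                keep = rng.choice(len(reps), config.rq2_max_per_cell, replace=False)
                use = [reps[i] for i in sorted(keep)]
            rows = discriminability_cell_rows(use, config.alpha)
            for row in rows:
                disc_by_pid[row["participant_id"]] = row
            for row in rows:
                cell_rows.append(
                    {
                        "measure": measure,
                        "domain": domain,
                        "statistic": "prop_discriminable",
                        "proportion": row["prop_discriminable"],
                        "variance": row["variance"],
                        "n_units": row["n_comparisons"],
                    }
                )
        width_props = None
        if 3 in config.run_rqs:
            if len(ivs) < 2:
                raise StageError(
                    "RQ3",
                    f"cell {measure}/{domain} has {len(ivs)} participant(s); "
                    "coverage needs at least 2",
                )
            width_props, cs = coverage_proportion(ivs, measure=measure, domain=domain)
            cell_rows.append(
                {
                    "measure": measure,
                    "domain": domain,
                    "statistic": cs.statistic,
                    "proportion": cs.proportion,
                    "variance": cs.variance,
                    "n_units": cs.n_units,
                }
            )
        for i, r in enumerate(cell_iv.itertuples()):
            disc = disc_by_pid.get(r.participant_id, {})
            precision_rows.append(
                {
                    "participant_id": r.participant_id,
                    "measure": measure,
                    "domain": domain,
                    "detectable_zero": det_flags[i],
                    "prop_discriminable": disc.get("prop_discriminable", np.nan),
                    "ci_width": r.width,
                    "width_proportion": (
                        float(width_props[i]) if width_props is not None else np.nan
                    ),
                }
            )

    cell_summaries = pd.DataFrame(
        cell_rows,
        columns=["measure", "domain", "statistic", "proportion", "variance", "n_units"],
    )
    participant_precision = pd.DataFrame(
        precision_rows,
        columns=KEY_COLUMNS
        + ["detectable_zero", "prop_discriminable", "ci_width", "width_proportion"],
    )
    map_widths = pd.DataFrame(
        map_rows, columns=["measure", "domain", "map_ci_width", "n_participants"]
    )

    emm_frames, contrast_frames = [], []
    statistic_of_rq = {1: "prop_diff_zero", 2: "prop_discriminable",
                       3: "ci_width_proportion_mean"}
    for rq in config.run_rqs:
        stat = statistic_of_rq[rq]
        rows = cell_summaries[cell_summaries["statistic"] == stat]
        if rows.empty or rows["measure"].nunique() < 2:
            continue
        try:
            fit = fit_weighted_lmm(MetaDataset.from_frame(rows))
        except Exception as err:  # surfaced, not swallowed
            raise StageError(f"meta:{stat}", str(err)) from err
        emms = estimated_marginal_means(fit)
        emms.insert(0, "statistic", stat)
        emms["tau2_domain"] = fit.tau2_domain
        emms["fit_method"] = fit.fit_method
        emm_frames.append(emms)
        contrasts = pairwise_contrasts(fit, alpha=config.alpha)
        contrasts.insert(0, "statistic", stat)
        contrast_frames.append(contrasts)

    meta_emms = (
        pd.concat(emm_frames, ignore_index=True) if emm_frames else pd.DataFrame()
    )
    meta_contrasts = (
        pd.concat(contrast_frames, ignore_index=True)
        if contrast_frames
        else pd.DataFrame()
    )

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "metric": config.score_spec.metric,
        "n_resamples": config.bootstrap.n_resamples,
        "rqs": list(config.run_rqs),
        "n_trials_scored": int(len(trials)),
        "n_participants_scored": int(len(scores)),
    }
    return ReportBundle(
        scores=scores,
        intervals=intervals,
        participant_precision=participant_precision,
        cell_summaries=cell_summaries,
        map_widths=map_widths,
        meta_emms=meta_emms,
        meta_contrasts=meta_contrasts,
        exclusion_report=excl.to_frame(),
        ground_truth=ground_truth,
        manifest=manifest,
    )


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write every bundle table as CSV plus the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in bundle.tables().items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written


def summarize_report(bundle: ReportBundle) -> str:
    """Plain-text per-measure summary of a study run."""
    lines = [
        f"precision study (seed {bundle.manifest['seed']}, "
        f"metric {bundle.manifest['metric']}, "
        f"{bundle.manifest['n_resamples']} resamples)",
        "",
    ]
    stat_label = {
        "prop_diff_zero": "detectable",
        "prop_discriminable": "discriminable",
        "ci_width_proportion_mean": "coverage",
    }
    for measure in sorted(bundle.scores["measure"].unique()):
        lines.append(f"{measure}:")
        mw = bundle.map_widths[bundle.map_widths["measure"] == measure]
        if not mw.empty:
            lines.append(
                "  modal CI width: "
                + ", ".join(
                    f"{r.domain}={r.map_ci_width:.3f}" for r in mw.itertuples()
                )
            )
        if not bundle.meta_emms.empty:
            for stat, label in stat_label.items():
                row = bundle.meta_emms[
                    (bundle.meta_emms["statistic"] == stat)
                    & (bundle.meta_emms["measure"] == measure)
                ]
                if not row.empty:
                    r = row.iloc[0]
                    lines.append(f"  {label}: EMM {r['emm']:.3f} (SE {r['se']:.3f})")
    skipped_rqs = sorted({1, 2, 3} - set(bundle.manifest["rqs"]))
    if skipped_rqs:
        lines.append("")
        lines.append(
            "skipped research questions (not requested): "
            + ", ".join(f"RQ{q}" for q in skipped_rqs)
        )
    if not bundle.meta_contrasts.empty:
        lines.append("")
        lines.append("largest Holm-significant contrasts:")
        sig = bundle.meta_contrasts[bundle.meta_contrasts["p_holm"] < 0.05]
        top = sig.reindex(
            sig["emm_difference"].abs().sort_values(ascending=False).index
        ).head(5)
        for r in top.itertuples():
            lines.append(
                f"  [{r.statistic}] {r.measure_1} vs {r.measure_2}: "
                f"{r.emm_difference:+.3f} (p_holm={r.p_holm:.4g})"
            )
    return "\n".join(lines) + "\n"
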