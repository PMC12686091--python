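"""The three per-cell precision statistics, plus the modal CI width.

For every measure x domain cell the pipeline asks:

* **detectability** — what proportion of participants' intervals exclude
  the metric's point of zero effect (PI = 0.5)?
* **discriminability** — for each participant, from what proportion of the
  other participants in the cell is their score detectably different
  (the bootstrap CI of the pairwise difference excludes 0)?
* **coverage** — how much of the observed score range does a typical
  interval span (interval width divided by the cell's range of point
  estimates)?

Each statistic is summarized as a proportion with a variance so the cells
can be meta-analyzed; proportions of exactly 0 or 1 and variances of
exactly 0 are offset by 0.001 to keep inverse-variance weights finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import gaussian_kde

from .boot_ci import IntervalEstimate, ReplicateSet, pairwise_difference_ci

__all__ = [
    "CellSummary",
    "offset_proportion",
    "offset_variance",
    "detectable_from_zero",
    "cell_proportion_detectable",
    "discriminability_proportions",
    "coverage_proportion",
    "map_width",
]

OFFSET = 0.001


@dataclass(frozen=True)
class CellSummary:
    """One meta-analysis row: a cell's proportion and its variance."""

    measure: str
    domain: str
    statistic: str
    proportion: float
    variance: float
    n_units: int

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("cell variance must be positive after offsetting")
        if self.n_units < 1:
            raise ValueError("a cell needs at least one unit")


def offset_proportion(p: float) -> float:
    """Nudge exact 0 / 1 proportions 0.001 into the interior."""
    if p == 0.0:
        return OFFSET
    if p == 1.0:
        return 1.0 - OFFSET
    return p


def offset_variance(v: float) -> float:
    # treat float-rounding residue as zero: a ~1e-30 variance would otherwise
    # dominate the inverse-variance weights
    return OFFSET if v < 1e-12 else v


def detectable_from_zero(
    interval: IntervalEstimate, null_value: float = 0.5
) -> bool:
    """True iff the interval excludes the null point.

    A bound exactly at the null does not count as detection.
    """
    return interval.lower > null_value or interval.upper < null_value


def cell_proportion_detectable(
    flags: np.ndarray | list[bool],
    *,
    measure: str = "",
    domain: str = "",
) -> CellSummary:
    """Proportion of detectable effects in a cell, with binomial variance."""
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("cell has no participants")
    p = float(flags.mean())
    variance = p * (1.0 - p) / n
    return CellSummary(
        measure=measure,
        domain=domain,
        statistic="prop_diff_zero",
        proportion=offset_proportion(p),
        variance=offset_variance(variance),
        n_units=n,
    )


def discriminability_proportions(
    replicate_sets: list[ReplicateSet],
    alpha: float = 0.05,
) -> tuple[np.ndarray, CellSummary | None]:
    """Per-participant discriminability in one cell.

    Every unordered pair is compared once via the paired-replicate
    difference interval; the pair is discriminable for both members iff
    the interval excludes 0 (the interval is antisymmetric, so the
    relation is symmetric). Participant i's proportion is over their n-1
    partners; its variance is the binomial p(1-p)/(n-1). Returns the
    per-participant (offset) proportions; the cell summary is built by the
    caller, which knows the measure/domain labels.
    """
    n = len(replicate_sets)
    if n < 2:
        raise ValueError("discriminability needs at least 2 participants in a cell")
    wins = np.zeros(n, dtype=int)
    for i, j in combinations(range(n), 2):
        ci = pairwise_difference_ci(replicate_sets[i], replicate_sets[j], alpha)
        if ci.lower > 0.0 or ci.upper < 0.0:
            wins[i] += 1
            wins[j] += 1
    props = wins / (n - 1)
    return props, None


def discriminability_cell_rows(
    replicate_sets: list[ReplicateSet], alpha: float = 0.05
) -> list[dict]:
    """Tidy per-participant rows (proportion + variance, offsets applied)."""
    props, _ = discriminability_proportions(replicate_sets, alpha)
    n = len(replicate_sets)
    rows = []
    for rep, p in zip(replicate_sets, props):
        variance = p * (1.0 - p) / (n - 1)
        rows.append(
            {
                "participant_id": rep.participant_id,
                "prop_discriminable": offset_proportion(float(p)),
                "variance": offset_variance(float(variance)),
                "n_comparisons": n - 1,
            }
        )
    return rows


def coverage_proportion(
    intervals: list[IntervalEstimate],
    *,
    measure: str = "",
    domain: str = "",
    range_over: str = "estimates",
) -> tuple[np.ndarray, CellSummary]:
    """Interval width as a share of the cell's observed score range.

    The observed range is max - min of the point estimates in the cell
    (``range_over="bounds"`` instead spans all interval bounds). Width
    proportions above 1 are legal and preserved. The cell proportion is
    their mean; its variance is the sample variance of the proportions
    divided by n (variance of the mean), offsets applied.
    """
    if len(intervals) < 2:
        raise ValueError("coverage needs at least 2 participants in a cell")
    estimates = np.array([iv.estimate for iv in intervals])
    if range_over == "bounds":
        lo = min(iv.lower for iv in intervals)
        hi = max(iv.upper for iv in intervals)
        observed_range = hi - lo
    else:
        observed_range = float(estimates.max() - estimates.min())
    if observed_range <= 0.0:
        raise ValueError("degenerate cell: observed score range is zero")
    widths = np.array([iv.width for iv in intervals])
    props = widths / observed_range
    mean = float(props.mean())
    variance = float(props.var(ddof=1) / props.size)
    summary = CellSummary(
        measure=measure,
        domain=domain,
        statistic="ci_width_proportion_mean",
        proportion=offset_proportion(mean),
        variance=offset_variance(variance),
        n_units=props.size,
    )
    return props, summary


def map_width(widths: np.ndarray | list[float], *, grid_size: int = 2048) -> float:
    """Modal CI width: mode of a Gaussian KDE over the widths.

    Silverman-bandwidth KDE, mode located by grid search over
    [min, max] with ``grid_size`` points. Degenerate (all-equal or single)
    samples return the common value directly.
    """
    widths = np.asarray(widths, dtype=float)
    if widths.size == 0:
        raise ValueError("map_width needs at least one width")
    if widths.size == 1 or np.ptp(widths) == 0.0:
        return float(widths[0])
    kde = gaussian_kde(widths, bw_method="silverman")
    grid = np.linspace(widths.min(), widths.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])
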