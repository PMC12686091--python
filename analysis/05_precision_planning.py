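#!/usr/bin/env python
"""Precision planning: SEm algebra, required CI widths, and error rates.

Three planning questions, independent of any particular dataset:
(1) what interval does the classical SEm route give an individual score;
(2) how narrow must an individual's CI be to separate adjacent bias
categories of the historical IAT D-score feedback cut-offs; and
(3) what false-positive/false-negative rates follow when comparing two
individuals' scores at a given measurement error. Writes a planning
table under results/planning/.
"""

import argparse
from pathlib import Path

import pandas as pd

from implicit_precision.sem_planner import (
    PROJECT_IMPLICIT_CUTOFFS,
    ErrorRateSimSpec,
    comparison_power,
    required_ci_width,
    sem,
    sem_interval,
    simulate_error_rates,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/planning"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

# (1) SEm worked example: D = 0.30, SD = 1.0, test-retest r = 0.50
sd, r = 1.0, 0.50
sem_value = sem(sd, r)
lo, hi = sem_interval(0.30, sem_value)
print(f"SEm(SD={sd}, r={r}) = {sem_value:.3f}; D = 0.30 -> CI ({lo:.2f}, {hi:.2f})")

# (2) required widths between adjacent feedback cut-offs
rows = []
for lo_label, hi_label, a, b in PROJECT_IMPLICIT_CUTOFFS.adjacent_pairs():
    w = required_ci_width(a, b)
    rows.append(
        {"from": lo_label, "to": hi_label, "cutoff_low": a, "cutoff_high": b,
         "required_ci_width": w}
    )
    print(f"separating {lo_label!r} from {hi_label!r} needs CI width <= {w:.1f}")
pd.DataFrame(rows).to_csv(args.out / "required_widths.csv", index=False)

# (3) error rates when comparing two individuals, per measurement SD
plan_rows = []
for msd in (0.1, 0.2, 0.3, 0.4):
    for true_diff in (0.0, 0.3, 0.65):
        fpr, fnr = simulate_error_rates(
            ErrorRateSimSpec(
                true_difference=true_diff, measurement_sd=msd,
                n_sims=100_000, seed=args.seed,
            )
        )
        plan_rows.append(
            {
                "measurement_sd": msd,
                "true_difference": true_diff,
                "false_positive_rate": fpr,
                # a miss rate is only meaningful when a true difference exists
                "false_negative_rate": fnr if true_diff > 0 else float("nan"),
                "analytic_power": comparison_power(true_diff, msd),
            }
        )
plan = pd.DataFrame(plan_rows)
plan.to_csv(args.out / "error_rates.csv", index=False)
print("\nerror rates for pairwise score comparisons (alpha = 0.05):")
print(plan.round(3).to_string(index=False))
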