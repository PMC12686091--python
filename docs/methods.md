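# Methods

## Problem

Implicit measures — the IAT, Brief IAT, Single-Target IAT, AMP, GNAT, and
evaluative priming task — are routinely interpreted at the level of single
participants ("this person shows a moderate bias"), yet such statements are
rarely accompanied by any quantification of how precisely an individual's
score is measured. This package provides that quantification: an interval
estimate for every participant's score, built from their own trial-level
data, plus the statistics needed to compare how precise different tasks are
and to plan how precise a task would need to be for a given inferential
goal.

## Scoring: the probabilistic index

All tasks are scored on one common metric, the probabilistic index (PI,
also known as the common-language effect size or Ruscio's A): the
probability that a randomly drawn response from condition pool B exceeds a
randomly drawn response from pool A, ties counted half,

    PI = ( #{(a, b) : b > a} + 0.5 · #{(a, b) : b = a} ) / (n_A · n_B).

PI equals the Mann–Whitney U statistic divided by n_A·n_B, lies in [0, 1],
and has 0.5 as the point of zero effect. Being rank-based, it applies
identically to latency pools and to binary evaluative responses, which is
what makes tasks with different native scales comparable. The
implementation uses midranks (O(n log n)); an exhaustive pair-enumeration
oracle is kept in the test suite and the two are checked for exact
agreement on random instances including heavy ties.

Native scores are available for comparison: the IAT-family D score
(mean latency difference between the two critical pools divided by the
inclusive SD of all critical-trial latencies, n−1 denominator, bounded in
[−2, 2]), the evaluative proportion difference, and the raw mean latency
difference. The D variant uses all critical trials with no error-penalty
replacement; error trials are retained for all metrics by default (a
`ScoreSpec` flag drops them), since rank-based scoring has no
error-correction step and the choice is exposed rather than hidden.
Orientation is fixed so that PI > 0.5 and D > 0 read in the same
direction (pool B larger).

## Per-participant intervals: the basic bootstrap

Each participant's trial-level data is the resampled distribution: a
replicate re-scores a with-replacement resample of their own trials, and
2000 replicates (the default) feed the basic (reverse-percentile) interval

    ( 2·θ̂ − Q₁₋α/₂ ,  2·θ̂ − Qα/₂ ),

with Q the empirical replicate quantile (linear/type-7 interpolation,
fixed for reproducibility) and α = 0.05. Design choices that were
genuinely open, and how they were settled:

* **Stratified resampling** (within each condition pool, preserving n_A
  and n_B) is the default: an unstratified resample can empty a pool,
  which no score survives. The unstratified variant is available behind a
  flag.
* **No clipping.** Basic bounds can fall outside [0, 1] for the PI; they
  are preserved as computed. Clipping would understate interval widths,
  which are the quantity of interest.
* **Degenerate resamples** (e.g. zero pooled SD for D) are redrawn, at
  most 100 times, then dropped with a count; a participant whose observed
  data admit no valid replicate raises a degenerate-data error.
* **Pairwise difference intervals** reuse each participant's cached 2000
  replicates, paired index by index. For independent participants this is
  statistically equivalent to re-bootstrapping each pair from raw trials
  and reduces the RQ-2 pair loop from O(n²) fresh bootstraps to O(n²)
  subtractions.
* Percentile and bias-corrected (BCa) intervals are implemented for
  sensitivity comparisons only.

Bootstrap seeds are derived per participant from the global seed and the
participant's identity (SHA-256 based), so results are invariant to row
order and to which other participants are present.

## The three precision statistics

For every measure × domain cell:

* **Detectability**: the proportion of participants whose 95% interval
  excludes the metric's zero-effect point (PI = 0.5). A bound exactly at
  the null does not count. Variance: binomial p(1−p)/n.
* **Discriminability**: for each participant, the proportion of the other
  participants in the cell from whom their score is detectably different
  (the paired-replicate difference interval excludes 0), over n−1
  comparisons; variance binomial over n−1.
* **Coverage**: each participant's interval width divided by the cell's
  observed range of point estimates; the cell value is the mean of these
  width proportions and its variance is the sample variance divided by n.
  Width proportions above 1 are legal and preserved. The observed range
  is taken over point estimates; a flag switches to the span of all
  interval bounds, since either reading of "observed range" is defensible.

Proportions of exactly 0 or 1 are offset to 0.001 / 0.999 and variances of
(numerically) zero to 0.001, so every cell carries a finite
inverse-variance weight into the meta-model. The variance floor treats
values below 1e−12 as zero: float-rounding residue on the order of 1e−30
would otherwise dominate the weights.

The **modal CI width** per cell is the mode of a Gaussian kernel density
estimate over the widths (Silverman bandwidth, grid search over
[min, max] with 2048 points) — a maximum-a-posteriori summary that is
robust to the long right tail of width distributions. Degenerate
(all-equal) samples return the common value.

## Meta-analytic comparison of measures

Cell (or participant-level) proportions y_k with variances v_k enter

    y_k = μ + β_measure(k) + u_domain(k) + ε_k,
    u_d ~ N(0, τ²),  ε_k ~ N(0, σ²·v_k),

i.e. measure as a fixed factor (the compared tasks are an exhaustive set)
and attitude domain as a random intercept (domains are a sample from a
larger population), weighted by inverse variance. The supplied variances
act as known *relative* variances with a residual scale σ² estimated —
the standard interpretation of weighted mixed models; a `fixed_scale`
mode pins σ² = 1, the classical meta-regression convention.

τ² is estimated by restricted maximum likelihood, profiled over the single
variance ratio λ = τ²/σ²: β and σ² have closed forms given λ, so the REML
criterion is minimized by a coarse log-grid search polished with bounded
Brent iteration (tolerance 1e−8, deterministic). If the optimum is at
λ ≈ 0 (τ² ≤ 1e−10) the fit collapses to weighted least squares and is
flagged `WLS-fallback` — with only three domain levels τ² is weakly
identified, and the flag is part of the public contract rather than a
hidden detail. The fit is validated in the tests against an independent
generalized-least-squares solve with the variance components plugged in.

Estimated marginal means per measure follow from the treatment-coded
fixed effects (the random intercept averages to zero); all 15 pairwise
differences for 6 measures use z-based p-values from the full
fixed-effect covariance — the degrees-of-freedom approximation for such
contrasts is not settled, and the normal reference is documented as a
possible divergence from df-corrected alternatives for small domain
counts. Holm's step-down correction (delegated to statsmodels, verified
against a brute-force enumeration oracle) controls the family-wise error
rate. σ² from exactly-zero residuals is floored at 1e−30 and contrasts
with |difference| or SE below 1e−12 are reported as p = 1, the tie-break
for degenerate all-identical inputs.

## SEm utilities and precision planning

The classical route to an individual interval is the standard error of
measurement, SEm = SD·√(1−r) with r the test–retest reliability, giving
score ± 1.96·SEm. It assumes one width for everyone, which is exactly
what the bootstrap route relaxes; both are provided.

Planning tools:

* `required_ci_width(c₁, c₂) = 2·(c₂ − c₁)`: the widest symmetric CI for
  which a score at one cut-off still excludes the other. Over the
  historical IAT feedback cut-offs (0 / 0.15 / 0.35 / 0.65 for
  no / weak / moderate / strong bias) this gives 0.3, 0.4 and 0.6 for the
  three adjacent separations.
* `simulate_error_rates`: draws pairs of observed scores (true scores a
  fixed difference apart plus independent N(0, σ²) measurement errors),
  declares a difference when the observed gap exceeds z·√2·σ (the √2 is
  the error inflation of a two-score comparison), and reports
  false-positive and false-negative rates; checked against the
  closed-form normal power.
* `dscore_cutoff_intervals`: the typical bootstrap CI at each cut-off,
  summarized (median by default) over participants whose point estimate
  lies within a tolerance (default ±0.02) of the cut-off. How such
  cut-off intervals are best constructed is not standardized; this
  neighborhood-summary reading keeps every knob (tolerance, summary
  functional) exposed.

## Synthetic data: what it emulates and what it does not

No public trial-level dataset ships with the package, so a generator
provides the test bed. Per participant i a latent condition shift
δ_i ~ N(μ_δ, τ_δ²) is drawn; latency tasks draw pool-A latencies from an
ex-Gaussian (Gaussian σ = 100 ms plus exponential tail with mean 150 ms
on a 600 ms base — the standard minimal reaction-time model) and pool-B
latencies from the same distribution shifted by δ_i; binary tasks apply
the shift on the logit scale to a Bernoulli response probability. Default
study populations use μ_δ = 80 ms, τ_δ = 60 ms (logit scale: 0.8 / 0.5),
putting typical true PIs near 0.6 with realistic person-to-person spread.
Trial budgets mirror the relative budgets of the six paradigms (per
condition pool: IAT 60, B-IAT 20, ST-IAT 38, AMP 36, GNAT 32, EPT 24), so
the qualitative mechanism — precision grows with trial count — is
reproduced by construction.

Each participant's true PI is recorded in a ground-truth table: for
binary tasks via the exact enumeration
p_B(1−p_A) + ½[p_Ap_B + (1−p_A)(1−p_B)]; for latency tasks by evaluating
the distribution of the difference of two independent ex-Gaussian draws
with a fixed-seed 10⁶-pair Monte Carlo (sorted and cached; each shift is
then a binary-search lookup accurate to ~10⁻³), since no convenient
closed form exists. `delta_for_pi` inverts the same cache, so calibration
cohorts can be placed at exact true-PI values. For equal-variance
Gaussian noise the closed form Φ(δ/(σ√2)) is also provided and
cross-checked by simulation.

What the generator does **not** emulate: empirical latency distributions
of real tasks (no fitting to real data), practice/transfer effects across
blocks, fast-guess or lapse processes, block-order effects, or any
process-level (e.g. diffusion) structure. Passing tests therefore show
that the pipeline's statistics behave correctly under a known, clean
generative model — unbiased recovery, nominal interval calibration at
large trial counts, correct orderings — not that any particular real task
attains a particular precision.

## Numerical and calibration checks

The acceptance suite ties the pipeline to its reference points at fixed
problem sizes, chosen to keep a full run on one CPU within a few minutes:

* basic-interval coverage of the true PI at 200 trials/role: 500
  participants split over true PI ∈ {0.5, 0.6, 0.75}, required to be
  within 3 Monte-Carlo standard errors of 0.95 (at these trial counts the
  basic bootstrap is very close to nominal; at 20–60 trials/role —
  realistic task budgets — coverage degrades to roughly 0.90, which is
  itself a finding about short tasks, consistent with known small-sample
  bootstrap bias);
* null-cohort detectability ≈ α within the same tolerance (detectability
  is 1 − coverage at the null);
* monotone precision across 20 → 80 → 320 trials/role (median width
  strictly falls, detectability of shifted effects strictly rises);
* exact agreement of PI with pair enumeration, of the REML fit with a
  known-τ² GLS solve (10⁻⁶), of Holm with step-down enumeration on all
  permutations of ≤ 5 p-values, and of simulated error rates with
  closed-form power at 10⁵ simulations;
* byte-identical report bundles for a repeated seeded run (checked at 12
  participants/cell and 500 resamples; determinism does not depend on
  size, and the library defaults remain 50/cell and 2000 resamples).

## Known limitations

* The exclusion-policy defaults (300–10000 ms window, >10% fast trials,
  0.80 accuracy, ≥2 trials per role) are common practice, not a claim
  about any specific study's criteria; they are fully configurable and
  the report reconciles every removed trial and participant.
* The discriminability statistic's binomial variance treats a
  participant's n−1 pairwise outcomes as independent, which they are not
  exactly; the shared-replicate pairing also makes the pair relation
  symmetric by construction.
* z-based contrast inference can be anti-conservative with very few
  domains; a df-corrected reference is deliberately not imposed.
* BCa is provided without an automatic acceleration constant (the
  jackknife requires raw trials, which the replicate cache does not
  retain); with acceleration 0 it is a bias-corrected percentile
  interval.
* Runtime: the RQ-2 pair loop is O(n²) per cell; a seeded per-cell
  subsample cap (`rq2_max_per_cell`) is available for very large cells
  and off by default.
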