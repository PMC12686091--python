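import numpy as np
import pytest

from implicit_precision.boot_ci import (
    BootstrapSpec,
    basic_interval,
    bootstrap_participant_ci,
    pairwise_difference_ci,
    percentile_interval,
    replicate_scores,
)
from implicit_precision.scoring import DegenerateDataError, ScoreSpec
from implicit_precision.synthetic_data import PopulationSpec, TaskTemplate, simulate_task_data


def _pools(n, delta, seed, sd=100.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(600, sd, n) + rng.exponential(150, n)
    b = rng.normal(600 + delta, sd, n) + rng.exponential(150, n)
    return a, b


class TestBasicInterval:
    def test_reverse_percentile_formula(self):
        # theta=0.6 with replicates engineered so Q(.025)=0.5, Q(.975)=0.8
        reps = np.linspace(0.5, 0.8, 1001)
        iv = basic_interval(0.6, reps, alpha=0.05)
        q_lo, q_hi = np.quantile(reps, [0.025, 0.975])
        assert iv.lower == pytest.approx(2 * 0.6 - q_hi)
        assert iv.upper == pytest.approx(2 * 0.6 - q_lo)
        # identity against an independent quantile route
        assert iv.lower + iv.upper == pytest.approx(4 * 0.6 - (q_hi + q_lo))

    def test_constant_replicates_zero_width(self):
        iv = basic_interval(0.7, np.full(100, 0.7))
        assert (iv.lower, iv.upper) == (0.7, 0.7)
        assert iv.width == 0.0

    def test_bounds_not_clipped_to_unit_interval(self):
        # extreme estimate with replicates hugging 1: basic bound exceeds 1
        reps = np.concatenate([np.full(90, 0.98), np.full(10, 0.7)])
        iv = basic_interval(0.98, reps)
        assert iv.upper > 1.0

    def test_mirror_of_percentile_interval(self):
        rng = np.random.default_rng(0)
        reps = rng.normal(0.6, 0.05, 2000)
        basic = basic_interval(0.6, reps)
        perc = percentile_interval(0.6, reps)
        assert basic.lower == pytest.approx(2 * 0.6 - perc.upper)
        assert basic.upper == pytest.approx(2 * 0.6 - perc.lower)


class TestReplicateScores:
    def test_seed_determinism(self):
        a, b = _pools(30, 80, seed=1)
        spec = ScoreSpec()
        boot = BootstrapSpec(n_resamples=200, seed=42)
        r1 = replicate_scores(a, b, spec, boot)
        r2 = replicate_scores(a, b, spec, boot)
        assert np.array_equal(r1.replicates, r2.replicates)

    def test_constant_data_pi_replicates_collapse(self):
        a = np.full(10, 500.0)
        b = np.full(10, 500.0)
        reps = replicate_scores(a, b, ScoreSpec(), BootstrapSpec(n_resamples=50, seed=0))
        assert np.allclose(reps.replicates, 0.5)

    def test_constant_data_d_is_degenerate(self):
        a = np.full(10, 500.0)
        b = np.full(10, 500.0)
        with pytest.raises(DegenerateDataError):
            replicate_scores(
                a, b, ScoreSpec(metric="D"), BootstrapSpec(n_resamples=50, seed=0)
            )

    def test_replicate_mean_near_estimate(self):
        a, b = _pools(200, 80, seed=2)
        reps = replicate_scores(a, b, ScoreSpec(), BootstrapSpec(n_resamples=2000, seed=3))
        se = reps.replicates.std(ddof=1) / np.sqrt(reps.replicates.size)
        assert abs(reps.replicates.mean() - reps.estimate) < 3 * se + 1e-3

    def test_unstratified_path_runs(self):
        a, b = _pools(20, 80, seed=4)
        reps = replicate_scores(
            a, b, ScoreSpec(), BootstrapSpec(n_resamples=100, seed=5, stratified=False)
        )
        assert reps.replicates.size == 100


class TestParticipantCI:
    def test_width_positive_and_shrinks_with_trials(self):
        medians = []
        for n in (20, 80, 320):
            widths = []
            for seed in range(12):
                a, b = _pools(n, 80, seed=seed)
                iv, _ = bootstrap_participant_ci(
                    a, b, ScoreSpec(), BootstrapSpec(n_resamples=500, seed=seed)
                )
                assert iv.width > 0
                widths.append(iv.width)
            medians.append(float(np.median(widths)))
        assert medians[0] > medians[1] > medians[2]

    def test_strong_effect_interval_excludes_half(self):
        # pi_true ~ 0.9: delta chosen so the shift dominates the noise
        template = TaskTemplate("IAT", "latency", 200, 200)
        pop = PopulationSpec(1, 320.0, 0.0, seed=6)
        trials, truth = simulate_task_data(template, pop)
        assert truth["pi_true"].iloc[0] > 0.85
        a = trials[trials["block_role"] == "A"]["latency_ms"].to_numpy()
        b = trials[trials["block_role"] == "B"]["latency_ms"].to_numpy()
        iv, _ = bootstrap_participant_ci(
            a, b, ScoreSpec(), BootstrapSpec(n_resamples=2000, seed=7)
        )
        assert iv.lower > 0.5


class TestPairwiseDifference:
    def _reps(self, delta, seed, n=200):
        a, b = _pools(n, delta, seed=seed)
        return replicate_scores(
            a, b, ScoreSpec(), BootstrapSpec(n_resamples=1000, seed=seed)
        )

    def test_same_participant_zero_width_at_zero(self):
        r = self._reps(80, seed=8)
        iv = pairwise_difference_ci(r, r)
        assert iv.estimate == 0.0
        assert iv.width == 0.0
        assert iv.contains(0.0)

    def test_antisymmetry(self):
        r1, r2 = self._reps(40, seed=9), self._reps(120, seed=10)
        ij = pairwise_difference_ci(r1, r2)
        ji = pairwise_difference_ci(r2, r1)
        assert ij.lower == pytest.approx(-ji.upper, abs=1e-12)
        assert ij.upper == pytest.approx(-ji.lower, abs=1e-12)

    def test_well_separated_participants_discriminable(self):
        # pi_true ~ 0.30 vs ~ 0.70
        r1, r2 = self._reps(-75, seed=11), self._reps(75, seed=12)
        iv = pairwise_difference_ci(r1, r2)
        assert iv.upper < 0.0

    def test_length_mismatch_rejected(self):
        r1 = self._reps(40, seed=13)
        a, b = _pools(50, 40, seed=14)
        r2 = replicate_scores(a, b, ScoreSpec(), BootstrapSpec(n_resamples=77, seed=1))
        with pytest.raises(ValueError, match="equal length"):
            pairwise_difference_ci(r1, r2)
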