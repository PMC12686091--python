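from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from implicit_precision.meta_model import (
    MetaDataset,
    estimated_marginal_means,
    fit_weighted_lmm,
    holm_adjust,
    pairwise_contrasts,
)

MEASURES = ["IAT", "BIAT", "STIAT", "AMP", "GNAT", "EPT"]
DOMAINS = ["politics", "race", "self"]


def _grid_dataset(means, tau2=0.0, noise_sd=0.0, seed=0, variances=None):
    """Balanced measures x domains dataset generated from the model."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(tau2), len(DOMAINS))
    rows = []
    for m in MEASURES:
        for j, d in enumerate(DOMAINS):
            v = 1.0 if variances is None else variances[len(rows) % len(variances)]
            y = means[m] + u[j] + rng.normal(0, noise_sd * np.sqrt(v))
            rows.append({"proportion": y, "variance": v, "measure": m, "domain": d})
    return MetaDataset.from_frame(pd.DataFrame(rows))


def gls_oracle(data: MetaDataset, tau2: float, sigma2: float):
    """Independent GLS solve with the variance components plugged in."""
    measures = sorted(set(data.measure))
    domains = sorted(set(data.domain))
    n = data.y.size
    x = np.ones((n, len(measures)))
    for j, m in enumerate(measures[1:], start=1):
        x[:, j] = (data.measure == m).astype(float)
    z = np.column_stack([(data.domain == d).astype(float) for d in domains])
    v_full = sigma2 * np.diag(data.variance) + tau2 * z @ z.T
    vi = np.linalg.inv(v_full)
    return np.linalg.solve(x.T @ vi @ x, x.T @ vi @ data.y)


class TestWeightedFit:
    def test_single_domain_equal_variance_means(self):
        # one domain, equal weights: fixed-effect means are arithmetic means
        rng = np.random.default_rng(1)
        rows = []
        for m in MEASURES:
            for y in rng.normal(0.5, 0.1, 4):
                rows.append(
                    {"proportion": y, "variance": 1.0, "measure": m, "domain": "race"}
                )
        frame = pd.DataFrame(rows)
        fit = fit_weighted_lmm(MetaDataset.from_frame(frame))
        emms = estimated_marginal_means(fit).set_index("measure")["emm"]
        for m in MEASURES:
            expected = frame.loc[frame["measure"] == m, "proportion"].mean()
            assert emms[m] == pytest.approx(expected, abs=1e-6)

    def test_known_weights_weighted_mean(self):
        # tau2 profile collapses to 0 here; weighted mean (1*0.4 + 3*0.6)/4
        frame = pd.DataFrame(
            {
                "proportion": [0.4, 0.6],
                "variance": [1.0, 1.0 / 3.0],
                "measure": ["IAT", "IAT"],
                "domain": ["race", "race"],
            }
        )
        fit = fit_weighted_lmm(MetaDataset.from_frame(frame))
        emm = estimated_marginal_means(fit)["emm"].iloc[0]
        assert emm == pytest.approx(0.55, abs=1e-8)

    def test_matches_known_tau2_gls_oracle(self):
        means = dict(zip(MEASURES, [0.9, 0.8, 0.6, 0.4, 0.3, 0.3]))
        data = _grid_dataset(means, tau2=0.01, noise_sd=0.05, seed=7,
                             variances=[0.5, 1.0, 2.0])
        fit = fit_weighted_lmm(data)
        oracle = gls_oracle(data, fit.tau2_domain, fit.sigma2)
        assert np.allclose(fit.coef, oracle, atol=1e-6)

    def test_equal_weights_tau_zero_equals_ols(self):
        means = dict(zip(MEASURES, [0.9, 0.8, 0.6, 0.4, 0.3, 0.3]))
        data = _grid_dataset(means, tau2=0.0, noise_sd=0.02, seed=3)
        fit = fit_weighted_lmm(data)
        if fit.tau2_domain == 0.0:
            x = np.ones((data.y.size, len(MEASURES)))
            for j, m in enumerate(sorted(MEASURES)[1:], start=1):
                x[:, j] = (data.measure == m).astype(float)
            ols = np.linalg.lstsq(x, data.y, rcond=None)[0]
            assert np.allclose(fit.coef, ols, atol=1e-8)
            assert fit.fit_method == "WLS-fallback"

    def test_parameter_recovery_over_replicates(self):
        # REML EMMs are unbiased for the generating means (100 replicates)
        means = dict(zip(MEASURES, [0.85, 0.75, 0.60, 0.45, 0.35, 0.30]))
        err = {m: [] for m in MEASURES}
        for rep in range(100):
            data = _grid_dataset(means, tau2=0.005, noise_sd=0.03, seed=100 + rep)
            fit = fit_weighted_lmm(data)
            emms = estimated_marginal_means(fit).set_index("measure")["emm"]
            for m in MEASURES:
                err[m].append(emms[m] - means[m])
        for m in MEASURES:
            bias = np.mean(err[m])
            se = np.std(err[m], ddof=1) / 10.0
            assert abs(bias) < max(4 * se, 0.01)

    def test_saturated_design_rejected(self):
        # one row per fixed-effect parameter leaves no residual information
        with pytest.raises(ValueError, match="cannot identify"):
            fit_weighted_lmm(
                MetaDataset(
                    y=np.array([0.5]),
                    variance=np.array([1.0]),
                    measure=np.array(["IAT"], dtype=object),
                    domain=np.array(["race"], dtype=object),
                )
            )
        with pytest.raises(ValueError, match="positive"):
            MetaDataset(
                y=np.array([0.5]),
                variance=np.array([0.0]),
                measure=np.array(["IAT"], dtype=object),
                domain=np.array(["race"], dtype=object),
            )


class TestEMMsAndContrasts:
    def _fit(self, shift=0.0, seed=11):
        means = dict(zip(MEASURES, np.array([0.9, 0.8, 0.6, 0.4, 0.3, 0.25]) + shift))
        return fit_weighted_lmm(
            _grid_dataset(means, tau2=0.004, noise_sd=0.02, seed=seed)
        ), means

    def test_emm_ordering_matches_generating_means(self):
        fit, means = self._fit()
        emms = estimated_marginal_means(fit).set_index("measure")["emm"]
        gen_order = sorted(MEASURES, key=lambda m: means[m])
        emm_order = list(emms.sort_values().index)
        assert emm_order == gen_order

    def test_adding_constant_shifts_every_emm(self):
        fit0, _ = self._fit(0.0)
        fit1, _ = self._fit(0.1)
        e0 = estimated_marginal_means(fit0).set_index("measure")["emm"]
        e1 = estimated_marginal_means(fit1).set_index("measure")["emm"]
        assert np.allclose(e1 - e0, 0.1, atol=1e-8)

    def test_fifteen_contrasts_for_six_measures(self):
        fit, _ = self._fit()
        table = pairwise_contrasts(fit)
        assert len(table) == 15
        assert (table["p_holm"] >= table["p_value"] - 1e-15).all()

    def test_contrast_sign_antisymmetry(self):
        fit, _ = self._fit()
        table = pairwise_contrasts(fit).set_index(["measure_1", "measure_2"])
        for (m1, m2), row in table.iterrows():
            # difference defined as EMM(m1) - EMM(m2)
            emms = estimated_marginal_means(fit).set_index("measure")["emm"]
            assert row["emm_difference"] == pytest.approx(emms[m1] - emms[m2], abs=1e-10)

    def test_identical_emms_give_unit_pvalues(self):
        frame = pd.DataFrame(
            {
                "proportion": [0.5] * 6,
                "variance": [1.0] * 6,
                "measure": ["IAT", "IAT", "IAT", "AMP", "AMP", "AMP"],
                "domain": DOMAINS * 2,
            }
        )
        fit = fit_weighted_lmm(MetaDataset.from_frame(frame))
        table = pairwise_contrasts(fit)
        assert table["emm_difference"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)


def holm_oracle(ps):
    """Step-down enumeration: sort, scale, cumulative max, cap."""
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(running, 1.0)
    return adj


class TestHolm:
    def test_hand_enumerated_example(self):
        assert np.allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    def test_matches_oracle_on_all_small_permutations(self):
        base = [0.001, 0.011, 0.04, 0.2, 0.8]
        for k in range(1, 6):
            for perm in permutations(base[:k]):
                ps = np.array(perm)
                assert np.allclose(holm_adjust(ps), holm_oracle(ps), atol=1e-12)

    def test_never_more_rejections_than_unadjusted(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ps = rng.random(8)
            adj = holm_adjust(ps)
            assert (adj >= ps - 1e-15).all()
            assert np.sum(adj < 0.05) <= np.sum(ps < 0.05)
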