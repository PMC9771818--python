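import numpy as np
import pytest
from scipy import stats

from transmeta.meta_engine import (
    MIXTURE_LABELS,
    classify_variant_heterogeneity,
    fit_heterogeneity_mixture,
    fit_memo_model,
    memo_scan,
    null_loglik,
    sign_concordance,
    weighted_z_meta,
    weighted_z_meta_table,
)
from transmeta.synthetic_data import (
    SimulationConfig,
    simulate_ancestry_freqs,
    simulate_cohort_summaries,
)


class TestWeightedZ:
    def test_single_study_identity(self):
        z, p = weighted_z_meta([1.7], [5000], [0.2], [0.9])
        assert z == pytest.approx(1.7)
        assert p == pytest.approx(2 * stats.norm.sf(1.7))

    def test_equal_weights_scale_by_sqrt_two(self):
        z, _ = weighted_z_meta([1.5, 1.5], [4000, 4000], [0.3, 0.3], [1, 1])
        assert z == pytest.approx(1.5 * np.sqrt(2))

    def test_worked_example(self):
        z, _ = weighted_z_meta([2.0, 1.0], [1000, 4000], [0.3, 0.3], [1.0, 1.0])
        assert z == pytest.approx(1.789, abs=1e-3)

    def test_matches_direct_formula_on_random_input(self, rng):
        for _ in range(50):
            K = rng.integers(1, 8)
            zk = rng.normal(size=K)
            n = rng.integers(500, 50_000, K).astype(float)
            p = rng.uniform(0.05, 0.95, K)
            r2 = rng.uniform(0.3, 1.0, K)
            w = np.sqrt(n * p * (1 - p) * r2)
            expected = np.sum(w * zk) / np.sqrt(np.sum(w**2))
            z, _ = weighted_z_meta(zk, n, p, r2)
            assert z == expected  # exact: same arithmetic contract

    def test_table_scan_agrees_with_per_variant(self, rng):
        cfg = SimulationConfig(seed=5, n_studies=10, n_variants=30)
        merged, _ = simulate_cohort_summaries(cfg, return_merged=True)
        zs, ps = weighted_z_meta_table(merged)
        for j in range(30):
            n = merged.n_per_study
            z, p = weighted_z_meta(merged.z[j], n, merged.freq[j], merged.rsq[j])
            assert zs[j] == pytest.approx(z, abs=1e-12)
            assert ps[j] == pytest.approx(p, abs=1e-12)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            weighted_z_meta([np.nan], [np.nan], [np.nan], [np.nan])


class TestMemoModel:
    def test_two_study_equal_weight_average(self):
        f = fit_memo_model(np.array([2.0, 4.0]), np.array([1.0, 1.0]), np.ones((2, 1)), 0, tau2=0.0)
        assert f.gamma[0] == pytest.approx(3.0)
        assert np.sqrt(f.cov_gamma[0, 0]) == pytest.approx(1 / np.sqrt(2))
        assert f.X == pytest.approx(18.0)
        assert f.df == 1

    def test_intercept_only_tau_zero_equals_inverse_variance(self, rng):
        for _ in range(20):
            K = int(rng.integers(3, 15))
            b = rng.normal(0, 0.1, K)
            s = rng.uniform(0.01, 0.2, K)
            f = fit_memo_model(b, s, np.ones((K, 1)), 0, tau2=0.0)
            w = 1 / s**2
            assert f.gamma[0] == pytest.approx(np.sum(w * b) / np.sum(w), abs=1e-12)
            assert f.cov_gamma[0, 0] == pytest.approx(1 / np.sum(w), abs=1e-12)

    def test_meta_regression_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm

        K = 30
        C = np.column_stack([np.ones(K), rng.normal(size=(K, 2))])
        b = rng.normal(0, 0.1, K)
        s = rng.uniform(0.02, 0.2, K)
        f = fit_memo_model(b, s, C, 2, tau2=0.0)
        res = sm.WLS(b, C, weights=1 / s**2).fit()
        np.testing.assert_allclose(f.gamma, res.params, atol=1e-10)
        np.testing.assert_allclose(f.cov_gamma, res.normalized_cov_params, atol=1e-10)

    def test_tau_profile_matches_grid_search_oracle(self, rng):
        # independent oracle: dense grid over the same criterion
        K = 25
        C = np.ones((K, 1))
        s = rng.uniform(0.05, 0.15, K)
        b = rng.normal(0, 1, K) * np.sqrt(s**2 + 0.05**2)
        for method in ("ml", "reml"):
            f = fit_memo_model(b, s, C, 0, method=method)
            grid = np.linspace(0, 100 * np.median(s**2), 40_001)
            crit = np.empty_like(grid)
            for i, t in enumerate(grid):
                v = s**2 + t
                w = 1 / v
                g = np.sum(w * b) / np.sum(w)
                ll = -0.5 * (np.sum(np.log(v)) + np.sum(w * (b - g) ** 2))
                if method == "reml":
                    ll -= 0.5 * np.log(np.sum(w))
                crit[i] = ll
            t_star = grid[np.argmax(crit)]
            assert f.tau2 == pytest.approx(t_star, abs=grid[1] * 2)

    def test_tau_zero_when_moment_estimate_negative(self, rng):
        # under-dispersed effects: heterogeneity estimate must clamp at 0
        K = 20
        s = np.full(K, 0.1)
        b = rng.normal(0, 0.02, K)  # far less spread than s implies
        f = fit_memo_model(b, s, np.ones((K, 1)), 0)
        assert f.tau2 == 0.0

    def test_too_few_studies_returns_none(self):
        C = np.column_stack([np.ones(3), np.arange(3.0)])
        assert fit_memo_model(np.zeros(3), np.ones(3), C, 2) is None

    def test_collinear_design_returns_none(self):
        C = np.column_stack([np.ones(6), np.ones(6)])
        assert fit_memo_model(np.zeros(6), np.ones(6), C, 1) is None

    def test_parameter_recovery_small(self, rng):
        # focused recovery check; the full-scale version lives in acceptance
        cfg = SimulationConfig(seed=2, n_studies=60, n_variants=200)
        fr = simulate_ancestry_freqs(cfg, np.random.default_rng(2))
        g = np.tile([0.1, 0.05, 0, 0, 0], (200, 1))
        merged, truth = simulate_cohort_summaries(
            cfg, fr, np.random.default_rng(2), gamma=g, tau=np.full(200, 0.02),
            return_merged=True,
        )
        est = np.array(
            [fit_memo_model(merged.beta[j], merged.se[j], truth.C, 1).gamma for j in range(200)]
        )
        mc_se = est.std(axis=0) / np.sqrt(200)
        assert abs(est[:, 0].mean() - 0.1) < 3 * mc_se[0]
        assert abs(est[:, 1].mean() - 0.05) < 3 * mc_se[1]


class TestMemoScan:
    def test_bonferroni_combination(self, rng):
        cfg = SimulationConfig(seed=3, n_studies=12, n_variants=5)
        merged, truth = simulate_cohort_summaries(cfg, return_merged=True)
        fit = memo_scan(merged.beta[0], merged.se[0], truth.C)
        M = len(fit.models)
        best = min(f.p for f in fit.models.values())
        assert fit.combined_p == pytest.approx(min(1.0, M * best))

    def test_single_model_passthrough(self):
        # 2 studies: only the intercept model is estimable
        b = np.array([0.1, 0.2])
        s = np.array([0.1, 0.1])
        C = np.column_stack([np.ones(2), np.arange(2.0), np.ones(2), np.ones(2), np.ones(2)])
        fit = memo_scan(b, s, C)
        assert list(fit.models) == [0]
        assert fit.combined_p == pytest.approx(fit.models[0].p)

    def test_p_monotone_decreasing_in_X_at_fixed_df(self):
        assert stats.chi2.sf(10, 2) < stats.chi2.sf(5, 2)


class TestHeterogeneityMixture:
    def _scan_set(self, gamma, tau, n_variants=80, seed=4, n_studies=60):
        cfg = SimulationConfig(seed=seed, n_studies=n_studies, n_variants=n_variants)
        fr = simulate_ancestry_freqs(cfg, np.random.default_rng(seed))
        merged, truth = simulate_cohort_summaries(
            cfg, fr, np.random.default_rng(seed), gamma=gamma, tau=tau, return_merged=True
        )
        fits = [memo_scan(merged.beta[j], merged.se[j], truth.C) for j in range(n_variants)]
        return fits

    def test_single_variant_posterior_normalised(self):
        fits = self._scan_set(None, None, n_variants=1)
        mix = fit_heterogeneity_mixture(fits)
        assert mix.q.shape == (1, 6)
        assert mix.q.sum() == pytest.approx(1.0)

    def test_homogeneous_strong_effects_select_intercept_model(self):
        g = np.zeros((80, 5))
        g[:, 0] = 0.08
        fits = self._scan_set(g, np.zeros(80))
        mix = fit_heterogeneity_mixture(fits)
        sel = mix.selected()
        frac_mr0 = np.mean([s == "MR_0" for s in sel])
        assert frac_mr0 >= 0.9

    def test_component_moderated_effects_detected_in_majority(self):
        g = np.zeros((80, 5))
        g[:, 0] = 0.08
        g[:, 1] = 0.05  # strong axis-1 moderation at these sample sizes
        fits = self._scan_set(g, np.zeros(80))
        mix = fit_heterogeneity_mixture(fits)
        sel = mix.selected()
        frac_mod = np.mean([s not in ("NULL", "MR_0") for s in sel])
        assert frac_mod > 0.5

    def test_classification_rules(self):
        fits = self._scan_set(None, None, n_variants=3)
        q_mr0 = np.array([0.05, 0.8, 0.05, 0.05, 0.03, 0.02])
        call = classify_variant_heterogeneity(fits[0], q_mr0)
        assert call.het_class == "homogeneous"

        q_mr2 = np.array([0.0, 0.1, 0.1, 0.7, 0.05, 0.05])
        # weak: selected MR_2 but no significant component coefficient
        fits[1].models[2].gamma = np.array([0.1, 0.001, 0.001])
        call = classify_variant_heterogeneity(
            fits[1], q_mr2, maf_by_ancestry={"EUR": 0.2, "EAS": 0.3}
        )
        assert call.het_class == "weak"

        # strong: significant component + polymorphic in two ancestries
        fits[2].models[1].gamma = np.array([0.1, 1.0])
        fits[2].models[1].cov_gamma = np.diag([0.01, 0.01])
        q_mr1 = np.array([0.0, 0.1, 0.8, 0.05, 0.03, 0.02])
        call = classify_variant_heterogeneity(
            fits[2], q_mr1, maf_by_ancestry={"EUR": 0.2, "EAS": 0.3, "AFR": 0.005}
        )
        assert call.het_class == "strong"
        assert call.moderating_components == [1]
        assert call.polymorphic_ancestries == 2

        # monomorphic elsewhere: cannot be called strong
        call = classify_variant_heterogeneity(
            fits[2], q_mr1, maf_by_ancestry={"EUR": 0.2, "EAS": 0.001}
        )
        assert call.het_class == "weak"


class TestSignConcordance:
    def test_identity_and_antisymmetry(self, rng):
        b = rng.normal(size=20)
        assert sign_concordance(b, b)[0] == 1.0
        assert sign_concordance(b, -b)[0] == 0.0

    def test_counting(self):
        a = np.ones(10)
        b = np.ones(10)
        b[:2] = -1
        prop, p = sign_concordance(a, b)
        assert prop == pytest.approx(0.8)
        assert p == pytest.approx(stats.binomtest(8, 10, 0.5).pvalue)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            sign_concordance([0.0, np.nan], [1.0, 1.0])
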