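"""Transforms, the heteroscedastic mixed model and group tests."""

import numpy as np
import pandas as pd
import pytest

from restspectra.stats import (cohens_d, fit_lme, group_tests,
                               make_feature_table, select_transform)
from conftest import covariate_frame, simulated_feature_table


class TestSelectTransform:
    def test_lognormal_prefers_log(self, rng):
        x = np.exp(rng.normal(0, 1, 500))
        assert select_transform(x, ["identity", "log"])[0] == "log"

    def test_normal_prefers_identity(self, rng):
        x = rng.normal(0, 1, 500)
        assert select_transform(x, ["identity", "log"])[0] == "identity"

    def test_constant_sample_raises(self):
        with pytest.raises(ValueError):
            select_transform(np.ones(50))

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            select_transform(np.arange(10))

    def test_atanh_clips_out_of_domain_with_warning(self):
        from restspectra.stats import TRANSFORMS

        with pytest.warns(UserWarning, match="clipped"):
            out = TRANSFORMS["atanh"](np.array([0.5, 1.0, -1.2]))
        assert np.all(np.isfinite(out))


class TestFitLME:
    def test_matches_statsmodels_mixedlm(self):
        """Fixed effects and ML log-likelihood agree with an independent
        mixed-model implementation on homoscedastic data."""
        import statsmodels.formula.api as smf

        table = simulated_feature_table(n=300, seed=42, beta_group=0.5)
        ours = fit_lme(table, model=2)
        sm = smf.mixedlm(
            "y ~ age_z + sex01 + iq_z + asd + asd:age_z + asd:sex01 "
            "+ asd:iq_z", table, groups=table["site"]).fit(reml=False)
        np.testing.assert_allclose(ours.beta, sm.fe_params.values, atol=1e-4)
        assert ours.loglik == pytest.approx(sm.llf, abs=1e-5)
        assert ours.sigma_site2 == pytest.approx(sm.cov_re.values[0, 0],
                                                 abs=1e-3)

    def test_gls_oracle_at_fixed_variance_components(self):
        """With variance components fixed, the betas equal closed-form GLS."""
        table = simulated_feature_table(n=150, seed=3)
        fit = fit_lme(table, model=1)
        from restspectra.stats import _design

        x, _ = _design(table, 1)
        y = table["y"].to_numpy()
        sites = pd.get_dummies(table["site"]).to_numpy(dtype=float)
        v = fit.sigma2 * np.eye(len(y)) + fit.sigma_site2 * sites @ sites.T
        vinv = np.linalg.inv(v)
        beta_gls = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
        np.testing.assert_allclose(fit.beta, beta_gls, atol=1e-6)

    def test_loglik_nesting_over_datasets(self):
        for seed in range(5):
            table = simulated_feature_table(n=120, seed=seed)
            res = group_tests(table, reml_confirm=False)
            ll1, ll2, ll3 = res.loglik
            assert ll2 >= ll1 - 1e-8
            assert ll3 >= ll2 - 1e-8

    def test_delta_fixed_at_one_reproduces_model2(self):
        table = simulated_feature_table(n=150, seed=9, delta=1.4)
        f2 = fit_lme(table, model=2)
        f3 = fit_lme(table, model=3, fixed_delta=1.0)
        assert f3.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_parameter_recovery_model3(self):
        """beta_group and delta recovered without systematic bias."""
        betas, deltas = [], []
        for seed in range(30):
            table = simulated_feature_table(n=400, seed=100 + seed,
                                            beta_group=0.5, delta=1.3)
            fit = fit_lme(table, model=3)
            betas.append(fit.beta[list(fit.coef_names).index("group")])
            deltas.append(fit.delta)
        assert np.mean(betas) == pytest.approx(0.5, abs=0.1)
        assert np.mean(deltas) == pytest.approx(1.3, abs=0.1)

    def test_zero_site_variance_boundary(self):
        """No site effect in truth: the fit lands at the boundary
        without crashing and with a near-zero variance estimate."""
        table = simulated_feature_table(n=200, seed=5, site_sd=0.0)
        fit = fit_lme(table, model=1)
        assert fit.converged
        assert fit.sigma_site2 < 0.05

    def test_single_group_rejected_for_model2(self):
        df = covariate_frame(50, seed=0)
        df["group"] = "ASD"
        table = make_feature_table(df, np.random.default_rng(0).normal(size=50))
        with pytest.raises(ValueError):
            fit_lme(table, model=2)


class TestGroupTests:
    def test_variance_effect_detected(self):
        """delta=1.5 at n=400 rejects the variance test in most runs."""
        hits = 0
        for seed in range(20):
            table = simulated_feature_table(n=400, seed=200 + seed, delta=1.5)
            res = group_tests(table, reml_confirm=False)
            hits += res.p_var < 0.05
        assert hits >= 16  # >= 80% power

    def test_duplicated_groups_have_zero_d(self):
        df = covariate_frame(60, seed=1)
        r = np.random.default_rng(2)
        y = r.normal(size=60)
        # make the NT half an exact copy of the ASD half
        half = 30
        y[half:] = y[:half]
        df = df.sort_values("group").reset_index(drop=True)
        table = make_feature_table(df, y)
        res = group_tests(table, reml_confirm=False)
        assert res.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_reml_f_tests_cover_group_terms(self):
        table = simulated_feature_table(n=200, seed=8, beta_group=0.8)
        res = group_tests(table)
        assert set(res.f_tests) == {"group", "group:age", "group:sex",
                                    "group:iq"}
        f_group, p_group = res.f_tests["group"]
        assert f_group > 0 and 0 <= p_group <= 1
        # a strong injected mean shift is confirmed by the F test
        assert p_group < 0.01


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d(1.0, 2.0, 50, 1.0, 3.0, 60) == 0.0

    def test_equal_sds_reduce_to_simple_form(self):
        assert cohens_d(2.0, 1.5, 30, 1.0, 1.5, 30) == pytest.approx(1.0 / 1.5)

    def test_iq_row_from_group_summaries(self):
        """ASD 104.0 +- 14.5 (n=212) vs NT 107.9 +- 13.1 (n=199)."""
        d = cohens_d(104.0, 14.5, 212, 107.9, 13.1, 199)
        assert round(d, 2) == -0.28

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            cohens_d(0, -1.0, 10, 0, 1.0, 10)
        with pytest.raises(ValueError):
            cohens_d(0, 1.0, 1, 0, 1.0, 10)
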