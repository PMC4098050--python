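"""Statistical core: bounded scaling, beta density, likelihood, fitting,
model selection and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from lvpwd import betareg
from lvpwd.betareg import (
    BoundedBetaParams,
    FittedModel,
    ModelSpec,
    SpecificationError,
)

from conftest import POLISH_AGE_SEX_SPEC, simulate_beta_design


class TestScaling:
    @pytest.mark.parametrize("mm,expected", [(8.5, 0.5), (8.3, 0.46), (6.5, 0.1)])
    def test_maps_linearly(self, mm, expected):
        assert betareg.scale_to_unit(mm) == pytest.approx(expected)

    @given(st.floats(min_value=6.0001, max_value=10.9999))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, mm):
        assert betareg.scale_to_mm(betareg.scale_to_unit(mm)) == pytest.approx(mm)

    @pytest.mark.parametrize("mm", [6.0, 11.0, 5.0, 12.0])
    def test_boundary_rejected(self, mm):
        with pytest.raises(betareg.BoundaryError):
            betareg.scale_to_unit(mm)


class TestDensity:
    def test_uniform_case(self):
        p = BoundedBetaParams(mu=0.5, phi=2.0)  # shapes (1, 1)
        assert betareg.beta_density(0.3, p) == pytest.approx(1.0)

    @pytest.mark.parametrize("mu", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("phi", [1.0, 5.0, 50.0])
    def test_normalization_and_moments(self, mu, phi):
        p = BoundedBetaParams(mu=mu, phi=phi)
        total, _ = integrate.quad(lambda y: betareg.beta_density(y, p), 0, 1)
        mean, _ = integrate.quad(lambda y: y * betareg.beta_density(y, p), 0, 1)
        m2, _ = integrate.quad(lambda y: y * y * betareg.beta_density(y, p), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(mu, abs=1e-6)
        assert m2 - mean**2 == pytest.approx(mu * (1 - mu) / (1 + phi), abs=1e-6)

    def test_quadrature_mean_at_fitted_values(self):
        p = BoundedBetaParams(mu=0.699, phi=3.87)
        mean, _ = integrate.quad(lambda y: y * betareg.beta_density(y, p), 0, 1)
        assert mean == pytest.approx(0.699, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BoundedBetaParams(mu=1.2, phi=1.0)
        with pytest.raises(ValueError):
            BoundedBetaParams(mu=0.5, phi=-1.0)


class TestLinearPredictors:
    def test_null_model(self):
        spec = ModelSpec(("intercept",), ("intercept",))
        mu, phi = betareg.linear_predictors(spec, ([0.0], [0.0]), {"age": 1.0})
        assert (mu, phi) == (0.5, 1.0)

    def test_hand_evaluated_coefficients(self):
        # eta_mean = -1.428 + .034*20 + 2.169 - .029*20 = 0.841 -> mu ~ 0.699
        beta = [-1.428, 0.034, 2.169, -0.029]
        gamma = [2.696, -0.030, -1.382, 0.032]
        mu, phi = betareg.linear_predictors(
            POLISH_AGE_SEX_SPEC, (beta, gamma), {"age": 20.0, "sex": 1.0})
        assert mu == pytest.approx(0.699, abs=5e-4)
        assert phi == pytest.approx(3.873, abs=5e-3)

    def test_uhz_female(self):
        spec = ModelSpec(("intercept", "age", "sex"), ("intercept",))
        mu, phi = betareg.linear_predictors(
            spec, ([-1.176, 0.013, 0.851], [1.432]), {"age": 20.0, "sex": 0.0})
        assert mu == pytest.approx(0.286, abs=5e-4)
        assert phi == pytest.approx(np.exp(1.432))

    def test_missing_covariate_named(self):
        with pytest.raises(SpecificationError, match="age"):
            betareg.linear_predictors(
                POLISH_AGE_SEX_SPEC, (np.zeros(4), np.zeros(4)), {"sex": 1.0})

    @given(st.floats(min_value=-5, max_value=5), st.floats(min_value=0.01, max_value=2))
    @settings(max_examples=50, deadline=None)
    def test_links_are_monotone(self, eta, delta):
        spec = ModelSpec(("intercept",), ("intercept",))
        mu0, phi0 = betareg.linear_predictors(spec, ([eta], [eta]), {})
        mu1, phi1 = betareg.linear_predictors(spec, ([eta + delta], [eta + delta]), {})
        assert mu1 > mu0 and phi1 > phi0


class TestLogLikelihood:
    def test_uniform_single_observation(self):
        spec = ModelSpec(("intercept",), ("intercept",))
        df = pd.DataFrame({"lvpwd_mm": [8.5]})
        # mu=0.5, phi must give shapes (1,1): phi=2 -> gamma0 = log 2
        ll = betareg.log_likelihood(spec, ([0.0], [np.log(2.0)]), df)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_additivity(self):
        spec = ModelSpec(("intercept",), ("intercept",))
        one = pd.DataFrame({"lvpwd_mm": [7.9]})
        two = pd.DataFrame({"lvpwd_mm": [7.9, 7.9]})
        coefs = ([0.3], [0.7])
        assert betareg.log_likelihood(spec, coefs, two) == pytest.approx(
            2 * betareg.log_likelihood(spec, coefs, one))

    def test_matches_per_row_density_oracle(self):
        data = simulate_beta_design(
            200, [-1.0, 0.02, 0.5, 0.0], [1.5, 0.0, -0.3, 0.0],
            POLISH_AGE_SEX_SPEC, seed=5)
        beta, gamma = [-0.9, 0.018, 0.4, 0.001], [1.2, 0.002, -0.2, 0.0]
        cov = data.drop(columns=["lvpwd_mm"])
        mu, phi = betareg.linear_predictors(POLISH_AGE_SEX_SPEC, (beta, gamma), cov)
        y = betareg.scale_to_unit(data["lvpwd_mm"].to_numpy())
        oracle = sum(
            stats.beta.logpdf(y[i], mu[i] * phi[i], (1 - mu[i]) * phi[i])
            for i in range(len(y)))
        ours = betareg.log_likelihood(POLISH_AGE_SEX_SPEC, (beta, gamma), data)
        assert ours == pytest.approx(oracle, abs=1e-10)


class TestFit:
    def test_null_model_recovery(self):
        spec = ModelSpec(("intercept",), ("intercept",))
        data = simulate_beta_design(5000, [0.0], [0.0],
                                    ModelSpec(("intercept",)), seed=42)
        fit = betareg.fit_model(spec, data)
        assert fit.converged
        se = fit.std_errors()
        assert abs(fit.beta[0]) < 3 * se[0]
        assert abs(fit.gamma[0]) < 3 * se[1]

    def test_matches_independent_implementation(self, polish_design, polish_fit):
        """Cross-check coefficients, SEs and loglik against statsmodels."""
        BetaModel = pytest.importorskip(
            "statsmodels.othermod.betareg").BetaModel
        cov = polish_design.drop(columns=["lvpwd_mm"])
        y = betareg.scale_to_unit(polish_design["lvpwd_mm"].to_numpy())
        X = betareg.design_matrix(POLISH_AGE_SEX_SPEC.mean_terms, cov)
        Z = betareg.design_matrix(POLISH_AGE_SEX_SPEC.precision_terms, cov)
        ref = BetaModel(y, X, exog_precision=Z).fit(disp=0)
        assert polish_fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        np.testing.assert_allclose(polish_fit.params, ref.params, atol=1e-4)
        np.testing.assert_allclose(polish_fit.std_errors(), ref.bse, rtol=1e-3)

    def test_too_few_observations(self):
        data = simulate_beta_design(6, [0.0, 0.0, 0.0, 0.0], np.zeros(4),
                                    POLISH_AGE_SEX_SPEC, seed=0)
        with pytest.raises(ValueError, match="n_obs"):
            betareg.fit_model(POLISH_AGE_SEX_SPEC, data)


class TestLRT:
    def test_identical_models(self, polish_fit):
        res = betareg.likelihood_ratio_test(polish_fit, polish_fit)
        assert res.statistic == 0.0 and res.df == 0 and res.p_value == 1.0

    def test_chi_square_quantile(self):
        spec_full = ModelSpec(("intercept", "age"))
        spec_nested = ModelSpec(("intercept",))
        mk = lambda spec, ll: FittedModel(
            spec=spec, beta=np.zeros(len(spec.mean_terms)), gamma=np.zeros(1),
            vcov=np.eye(spec.n_coef), loglik=ll, pseudo_r2=0.0, n_obs=100,
            converged=True)
        res = betareg.likelihood_ratio_test(mk(spec_nested, 0.0),
                                            mk(spec_full, 3.841 / 2))
        assert res.df == 1
        assert res.p_value == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self, polish_fit):
        other = ModelSpec(("intercept", "bsa"))
        fake = FittedModel(spec=other, beta=np.zeros(2), gamma=np.zeros(1),
                           vcov=np.eye(3), loglik=0.0, pseudo_r2=0.0,
                           n_obs=polish_fit.n_obs, converged=True)
        with pytest.raises(SpecificationError):
            betareg.likelihood_ratio_test(fake, polish_fit)

    def test_full_dominates_nested(self, polish_design, polish_fit):
        nested = betareg.fit_model(
            ModelSpec(("intercept", "age", "sex"), ("intercept",)), polish_design)
        assert polish_fit.loglik >= nested.loglik - 1e-6


class TestBackwardSelect:
    def test_pure_sex_effect_drops_age(self):
        data = simulate_beta_design(
            5000, [-0.5, 0.0, 1.0, 0.0], [1.5, 0.0, 0.0, 0.0],
            POLISH_AGE_SEX_SPEC, seed=11)
        res = betareg.backward_select(POLISH_AGE_SEX_SPEC, data)
        assert "sex" in res.fit.spec.mean_terms
        assert "age" not in res.fit.spec.mean_terms
        assert "age:sex" not in res.fit.spec.mean_terms

    def test_alpha_one_keeps_start(self, polish_design):
        res = betareg.backward_select(POLISH_AGE_SEX_SPEC, polish_design, alpha=1.0)
        assert res.fit.spec == POLISH_AGE_SEX_SPEC
        assert res.trace == []

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            betareg.backward_select(
                POLISH_AGE_SEX_SPEC,
                pd.DataFrame(columns=["age", "sex", "lvpwd_mm"]))


class TestPseudoR2:
    def test_intercept_only_is_zero(self, polish_design):
        fit = betareg.fit_model(ModelSpec(("intercept",)), polish_design)
        assert fit.pseudo_r2 == 0.0

    def test_near_deterministic_response_approaches_one(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(18, 75, size=2000)
        spec = ModelSpec(("intercept", "age"), ("intercept",))
        mu, phi = betareg.linear_predictors(
            spec, ([-2.0, 0.05], [np.log(5000.0)]), {"age": age})
        y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-9, 1 - 1e-9)
        data = pd.DataFrame({"age": age, "lvpwd_mm": 6 + 5 * y})
        fit = betareg.fit_model(spec, data)
        assert fit.pseudo_r2 > 0.95


class TestDiagnostics:
    def test_duplicates_get_identical_values(self, polish_design):
        dup = pd.concat([polish_design, polish_design.iloc[:1]],
                        ignore_index=True)
        fit = betareg.fit_model(POLISH_AGE_SEX_SPEC, dup)
        diag = betareg.diagnostics(fit, dup)
        n = len(polish_design)
        assert diag.residuals[n] == pytest.approx(diag.residuals[0])
        assert diag.leverage[n] == pytest.approx(diag.leverage[0])
        assert diag.cooks_distance[n] == pytest.approx(diag.cooks_distance[0])

    def test_leverage_trace_near_coefficient_count(self):
        """Generalized-leverage trace ~ parameter count on data whose
        responses stay well inside the bounds."""
        from lvpwd import cohort

        recipe = cohort.CohortRecipe.default("uhz", seed=5).with_counts(1000, 1000)
        data = cohort.to_design(cohort.generate_cohort(recipe))
        spec = ModelSpec(("intercept", "age", "sex"), ("intercept",))
        fit = betareg.fit_model(spec, data)
        diag = betareg.diagnostics(fit, data)
        total = float(np.sum(diag.leverage))
        assert total == pytest.approx(spec.n_coef, rel=0.10)

    def test_gross_outlier_dominates_cooks_distance(self):
        """A near-ceiling wall thickness injected into a female record is the
        most influential point of an otherwise clean simulated fit."""
        from lvpwd import cohort

        recipe = cohort.CohortRecipe.default("uhz", seed=14).with_counts(150, 150)
        data = cohort.to_design(cohort.generate_cohort(recipe))
        spec = ModelSpec(("intercept", "age", "sex"), ("intercept",))
        target = int(data.index[data.sex == 0.0][0])
        data.loc[target, "lvpwd_mm"] = 10.95
        fit = betareg.fit_model(spec, data)
        diag = betareg.diagnostics(fit, data)
        assert int(np.argmax(diag.cooks_distance)) == target
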