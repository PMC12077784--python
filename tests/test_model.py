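"""Likelihood construction, BFGS fitting, Wald/delta inference, model classes."""

import numpy as np
import pytest
import statsmodels.api as sm

from previnc.data import AggregatedPrevalenceTable
from previnc.model import (
    DifferentialMortalityIncidenceModel,
    FitResult,
    NonDifferentialIncidenceModel,
    PrevalenceSurfaceModel,
    binom_negloglik,
    delta_method,
    fit_ml,
    logit_linear_fit,
    wald_ci,
)
from previnc.prevalence import prevalence_nondiff
from previnc.rates import GompertzRate, MortalityScenario, expit
from previnc.simulate import SimulationDesign, simulate_counts


class TestBinomialKernel:
    def test_symmetric_coin(self):
        # kernel without the binomial coefficient: -2 log(1/2)
        assert binom_negloglik([0.5], [2], [1]) == pytest.approx(2 * np.log(2))

    def test_saturated_proportions_minimize(self, rng):
        n = np.array([50, 80, 120])
        c = np.array([5, 20, 90])
        best = binom_negloglik(c / n, n, c)
        for _ in range(200):
            p = np.clip(c / n + rng.normal(0, 0.02, 3), 1e-6, 1 - 1e-6)
            assert binom_negloglik(p, n, c) >= best

    def test_impossible_prevalence_penalized_finite(self):
        val = binom_negloglik([0.0], [10], [3])
        assert np.isfinite(val) and val >= 1e10

    def test_zero_count_cells_allowed_at_boundary(self):
        assert binom_negloglik([0.0], [10], [0]) == 0.0


class TestFitMl:
    def test_quadratic_objective(self):
        res = fit_ml(lambda x: (x[0] - 3.0) ** 2, [0.0])
        assert res.params[0] == pytest.approx(3.0, abs=1e-6)
        assert res.vcov[0, 0] == pytest.approx(0.5, rel=1e-4)
        assert res.converged

    def test_infinite_start_rejected(self):
        with pytest.raises(ValueError):
            fit_ml(lambda x: float(np.sum(x**2)), [np.inf])

    def test_flat_likelihood_reported(self):
        with pytest.raises(RuntimeError, match="singular|flat"):
            fit_ml(lambda x: (x[0] + x[1]) ** 2 + 1e-9 * 0, [1.0, -1.0])


class TestWaldAndDelta:
    def test_standard_normal_interval(self):
        fit = FitResult(np.array([0.0]), np.array([[1.0]]), 0.0, True, 1, "ok")
        lo, hi = wald_ci(fit, 0)
        assert lo == pytest.approx(-1.95996, abs=1e-5)
        assert hi == pytest.approx(1.95996, abs=1e-5)

    def test_negative_variance_rejected(self):
        fit = FitResult(np.array([0.0]), np.array([[-1.0]]), 0.0, True, 1, "ok")
        with pytest.raises(ValueError):
            wald_ci(fit, 0)

    @pytest.mark.parametrize(
        "grad, vcov, expected",
        [
            ([2.0], [[1.0]], 4.0),
            ([1.0], [[0.37]], 0.37),
            ([1.0, 1.0], [[1.0, 0.0], [0.0, 1.0]], 2.0),
        ],
    )
    def test_delta_method_quadratic_form(self, grad, vcov, expected):
        assert delta_method(grad, vcov) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            delta_method([1.0, 2.0], [[1.0]])


class TestLogitLinearFit:
    def test_exact_recovery(self):
        a_start = np.arange(20, 65, 5)
        mid = a_start + 2.5
        p = expit(-5.0 + 0.1 * mid)
        n = np.full_like(a_start, 10**7)
        table = AggregatedPrevalenceTable(a_start, a_start + 4, n, np.round(n * p).astype(int))
        b0, b1 = logit_linear_fit(table)
        assert b0 == pytest.approx(-5.0, abs=1e-3)
        assert b1 == pytest.approx(0.1, abs=1e-4)

    def test_coalminers_descriptive_fit(self, coalminers):
        b0, b1 = logit_linear_fit(coalminers)
        assert b0 == pytest.approx(-7.02, abs=5e-3)
        assert b1 == pytest.approx(0.110, abs=5e-4)

    def test_derived_incidence_positive_over_working_ages(self, coalminers):
        b0, b1 = logit_linear_fit(coalminers)
        a = np.linspace(20, 65, 46)
        i = b1 * expit(b0 + b1 * a)
        assert np.all(np.isfinite(i)) and np.all(i > 0)

    def test_boundary_proportion_rejected(self):
        table = AggregatedPrevalenceTable([20, 25], [24, 29], [10, 10], [0, 3])
        with pytest.raises(ValueError):
            logit_linear_fit(table)


class TestNonDifferentialModel:
    def test_coalminers_estimates(self, coalminers):
        res = NonDifferentialIncidenceModel(coalminers).fit()
        assert res.converged
        assert res.params[0] == pytest.approx(-7.8234, abs=2e-4)
        assert res.params[1] == pytest.approx(0.075580, abs=2e-6)

    def test_local_optimality_of_reported_optimum(self, coalminers, rng):
        model = NonDifferentialIncidenceModel(coalminers)
        res = model.fit()
        best = model.negloglik(res.params)
        for _ in range(1000):
            perturbed = res.params * (1 + rng.uniform(-0.1, 0.1, 2))
            assert model.negloglik(perturbed) >= best - 1e-9

    def test_fitted_prevalence_tracks_observed_cloud(self, coalminers):
        res = NonDifferentialIncidenceModel(coalminers).fit()
        dev = np.abs(res.fitted_prevalence() - coalminers.proportions)
        assert dev.max() < 0.03

    def test_incidence_curve_monotone_and_bracketing(self, coalminers):
        res = NonDifferentialIncidenceModel(coalminers).fit()
        curve = res.incidence(np.linspace(25, 60, 8))
        assert np.all(np.diff(curve["incidence"]) > 0)  # positive slope estimate
        assert np.all(curve["ci_lower"] <= curve["incidence"])
        assert np.all(curve["incidence"] <= curve["ci_upper"])
        assert np.all(curve["ci_lower"] > 0)  # log-scale interval keeps bounds positive

    def test_parameter_recovery_at_large_n(self):
        truth = GompertzRate(-7.823, 0.0756)
        design = SimulationDesign(
            truth=truth, scenario=MortalityScenario("nondifferential"),
            n_per_group=10**6, seed=11,
        )
        res = NonDifferentialIncidenceModel(simulate_counts(design)).fit()
        for est, se, true in zip(res.params, res.bse, [-7.823, 0.0756]):
            assert abs(est - true) < 3 * se

    def test_ci_width_shrinks_with_root_n(self):
        truth = GompertzRate(-7.8, 0.076)
        design = SimulationDesign(
            truth=truth, scenario=MortalityScenario("nondifferential"),
            n_per_group=5000, seed=7,
        )
        t1 = simulate_counts(design)
        t2 = AggregatedPrevalenceTable(t1.age_start, t1.age_end, 2 * t1.n, 2 * t1.c)
        w1 = np.diff(NonDifferentialIncidenceModel(t1).fit().conf_int(), axis=1)
        w2 = np.diff(NonDifferentialIncidenceModel(t2).fit().conf_int(), axis=1)
        np.testing.assert_allclose(w1 / w2, np.sqrt(2), rtol=0.05)

    def test_summary_mentions_parameters(self, coalminers):
        text = NonDifferentialIncidenceModel(coalminers).fit().summary()
        assert "gamma0" in text and "gamma1" in text and "converged: True" in text


class TestDifferentialModel:
    def test_equal_mortality_reduces_to_scenario_one(self, coalminers, mortality_general):
        m = mortality_general
        res_nd = NonDifferentialIncidenceModel(coalminers).fit()
        res_dm = DifferentialMortalityIncidenceModel(coalminers, m1=m, m=m).fit()
        np.testing.assert_allclose(res_dm.params, res_nd.params, atol=1e-4)

    def test_coalminers_differential_estimates(
        self, coalminers, mortality_general, mortality_diseased
    ):
        """Excess mortality of the diseased removes cases before observation,
        so the maximum-likelihood incidence is higher and steeper than under
        the non-differential assumption."""
        res = DifferentialMortalityIncidenceModel(
            coalminers, m1=mortality_diseased, m=mortality_general
        ).fit()
        nd = NonDifferentialIncidenceModel(coalminers).fit()
        assert res.converged
        assert res.params[1] > nd.params[1]
        assert res.incidence(np.array([60.0]))["incidence"].iloc[0] > \
            nd.incidence(np.array([60.0]))["incidence"].iloc[0]

    def test_recovery_simulation_small_bias(self, mortality_general, mortality_diseased):
        truth = GompertzRate(-8.0, 0.085)
        scenario = MortalityScenario(
            "diseased_and_general", m1=mortality_diseased, m=mortality_general
        )
        design = SimulationDesign(truth=truth, scenario=scenario, n_per_group=10**5, seed=3)
        res = DifferentialMortalityIncidenceModel(
            simulate_counts(design), m1=mortality_diseased, m=mortality_general
        ).fit()
        assert abs(res.params[1] - 0.085) < 0.002


class TestPrevalenceSurfaceModel:
    def test_matches_logistic_regression_oracle(
        self, diabetes, diabetes_mortality, diabetes_rate_ratio
    ):
        """The surface likelihood is a binomial GLM with logit link, so the
        generic BFGS fit must land on the IRLS solution."""
        res = PrevalenceSurfaceModel(diabetes, m=diabetes_mortality, R=diabetes_rate_ratio).fit()
        a = diabetes.midpoints
        X = np.column_stack([np.ones_like(a), diabetes.year - 2009, a, a**2])
        glm = sm.GLM(
            np.column_stack([diabetes.c, diabetes.n - diabetes.c]), X,
            family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(res.params, glm.params, rtol=1e-6)
        np.testing.assert_allclose(res.bse, glm.bse, rtol=2e-3)

    def test_year_column_required(self, coalminers, diabetes_mortality, diabetes_rate_ratio):
        with pytest.raises(ValueError, match="year"):
            PrevalenceSurfaceModel(coalminers, m=diabetes_mortality, R=diabetes_rate_ratio)

    def test_incidence_table_shape_and_flags(
        self, diabetes, diabetes_mortality, diabetes_rate_ratio
    ):
        res = PrevalenceSurfaceModel(diabetes, m=diabetes_mortality, R=diabetes_rate_ratio).fit()
        curve = res.incidence()
        assert list(curve["age"]) == list(np.arange(22.5, 98.0, 5.0))
        assert (curve["se"] > 0).all()
        assert not curve["flagged"].any()
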