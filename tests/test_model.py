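"""Estimator, hazard ratios, sojourn times, AIC and LR testing."""

import numpy as np
import pytest

import panelmsm as pm
from panelmsm.model import FitResult, Z95, likelihood_ratio_test

from conftest import records_frame, two_state_params


def make_fit(structure, alpha, terms=(), beta=None, cov=None, loglik=-1.0):
    params = pm.ModelParameters.from_arrays(structure, alpha, beta, terms)
    K = len(structure)
    n_params = K * (1 + len(terms))
    theta = np.concatenate([np.asarray(alpha, float),
                            np.zeros(n_params - K) if beta is None
                            else np.asarray(beta, float).ravel()])
    return FitResult(params=params, loglik=loglik, n_params=n_params,
                     covariance=cov, converged=True, theta=theta,
                     terms=tuple(terms), n_individuals=1)


class TestCountParameters:
    @pytest.mark.parametrize("terms,expected", [
        ((), 14),
        (pm.DESIGN_TERMS, 140),
        (("slum:Viwandani",), 28),
    ])
    def test_parameter_counts(self, structure, terms, expected):
        assert pm.count_parameters(structure, terms) == expected


class TestLikelihoodRatioTest:
    def test_identical_fits_give_zero_chisq_p_one(self, structure):
        null = make_fit(structure, np.full(14, -5.0), loglik=-1000.0)
        full = make_fit(structure, np.full(14, -5.0), terms=("age",),
                        loglik=-1000.0)
        res = likelihood_ratio_test(null, full)
        assert res.chisq == 0.0 and res.p_value == 1.0

    def test_paper_scale_degrees_of_freedom(self, structure):
        """Null (baselines only) vs full (all nine covariate columns):
        140 - 14 = 126 degrees of freedom."""
        null = make_fit(structure, np.full(14, -5.0), loglik=-1000.0)
        full = make_fit(structure, np.full(14, -5.0), terms=pm.DESIGN_TERMS,
                        loglik=-990.0)
        assert likelihood_ratio_test(null, full).df == 126

    def test_chisq_arithmetic_and_full_precision_p(self, structure):
        null = make_fit(structure, np.full(14, -5.0), loglik=-1000.0)
        full = make_fit(structure, np.full(14, -5.0),
                        terms=("slum:Viwandani",), loglik=-990.0)
        res = likelihood_ratio_test(null, full)
        assert res.chisq == pytest.approx(20.0)
        assert res.df == 14
        assert 0.0 < res.p_value < 1.0  # stored numerically, never truncated

    def test_worse_full_model_signals_failed_optimization(self, structure):
        null = make_fit(structure, np.full(14, -5.0), loglik=-990.0)
        full = make_fit(structure, np.full(14, -5.0), terms=("age",),
                        loglik=-1000.0)
        with pytest.raises(ValueError, match="optimization failed"):
            likelihood_ratio_test(null, full)


class TestHazardRatios:
    def test_wald_interval_back_solves_reported_row(self, structure):
        """beta = ln 1.390 with SE 0.0217 gives CI (1.332, 1.450)."""
        K, terms = 14, ("slum:Viwandani",)
        beta = np.zeros((1, K))
        k13 = structure.index((1, 3))
        beta[0, k13] = np.log(1.390)
        cov = np.zeros((2 * K, 2 * K))
        cov[K + k13, K + k13] = 0.0217 ** 2
        fit = make_fit(structure, np.full(K, -5.0), terms, beta, cov)
        hr = pm.hazard_ratios(fit)
        row = hr[(hr.from_state == 1) & (hr.to_state == 3)].iloc[0]
        assert row.hr == pytest.approx(1.390, abs=1e-9)
        assert row.ci_low == pytest.approx(1.332, abs=5e-4)
        assert row.ci_high == pytest.approx(1.450, abs=5e-4)

    def test_null_effect_interval_contains_one(self, structure):
        K = 14
        cov = np.eye(2 * K) * 0.01
        fit = make_fit(structure, np.full(K, -5.0), ("age",),
                       np.zeros((1, K)), cov)
        hr = pm.hazard_ratios(fit)
        assert np.allclose(hr.hr, 1.0)
        assert np.all((hr.ci_low < 1.0) & (hr.ci_high > 1.0))

    def test_missing_covariance_is_an_error(self, structure):
        fit = make_fit(structure, np.full(14, -5.0), ("age",),
                       np.zeros((1, 14)), cov=None)
        with pytest.raises(ValueError, match="covariance unavailable"):
            pm.hazard_ratios(fit)

    def test_invariant_to_baseline_rescaling(self, structure):
        """Scaling every baseline intensity leaves each HR unchanged."""
        K, terms = 14, ("slum:Viwandani",)
        beta = np.full((1, K), 0.3)
        cov = np.eye(2 * K) * 0.01
        h1 = pm.hazard_ratios(
            make_fit(structure, np.full(K, -5.0), terms, beta, cov))
        h2 = pm.hazard_ratios(
            make_fit(structure, np.full(K, -5.0) + np.log(3.0), terms, beta, cov))
        np.testing.assert_allclose(h1.hr, h2.hr)


class TestSojournTimes:
    def test_reciprocal_of_total_exit_rate(self, structure):
        # every transition out of state 1 at equal rates summing to 0.125/day
        alpha = np.full(14, -20.0)
        for pair in ((1, 3), (1, 5), (1, 7)):
            alpha[structure.index(pair)] = np.log(0.125 / 3)
        fit = make_fit(structure, alpha)
        tab = pm.mean_sojourn_times(fit)
        assert tab[tab.state == 1].mean_days.iloc[0] == pytest.approx(8.0)

    def test_delta_method_on_single_exit_state(self):
        """Rate 0.1/day with SE(log rate) 0.2: mean 10 days, SE 2 days."""
        structure = pm.TransitionStructure(((1, 3),))
        cov = np.array([[0.2 ** 2]])
        fit = make_fit(structure, [np.log(0.1)], cov=cov)
        row = pm.mean_sojourn_times(fit).iloc[0]
        assert row.mean_days == pytest.approx(10.0)
        assert row.se == pytest.approx(2.0)
        assert 0 < row.ci_low <= row.mean_days <= row.ci_high
        np.testing.assert_allclose(
            [row.ci_low, row.ci_high],
            [10 * np.exp(-Z95 * 0.2), 10 * np.exp(Z95 * 0.2)])

    def test_absorbing_state_rejected(self, structure):
        fit = make_fit(structure, np.full(14, -5.0))
        with pytest.raises(ValueError, match="undefined for the absorbing"):
            pm.mean_sojourn_times(fit, states=[1, 7])


class TestFitting:
    def test_fit_improves_on_crude_initializer_and_aic_identity(self):
        cfg = pm.SimulationConfig(n_individuals=150, horizon=1440, seed=9)
        datasets, _, _ = pm.generate_dataset(cfg)
        est = pm.PanelMarkovModel(compute_covariance=False).fit(
            datasets["Female"])
        assert est.converged_
        assert est.loglik_ >= est.initial_loglik_
        assert est.aic_ == 2 * est.n_params_ - 2 * est.loglik_
        assert est.n_params_ == 14

    def test_sklearn_get_set_params_round_trip(self):
        est = pm.PanelMarkovModel(covariate_terms=("age",), tol=1e-6)
        cloned = pm.PanelMarkovModel(**est.get_params())
        assert cloned.get_params() == est.get_params()

    def test_two_state_mle_matches_closed_form(self):
        """With only 1->3 observed over single intervals the MLE of the rate
        solves the binomial panel likelihood; oracle by direct 1-d search."""
        from scipy.optimize import minimize_scalar
        rows = []
        # 30 individuals observed once after 100 days, 11 made the move
        for i in range(30):
            rows += [(f"i{i}", 0.0, 1), (f"i{i}", 100.0, 3 if i < 11 else 1)]
        data = pm.PanelDataset(records_frame(rows), "Female")
        est = pm.PanelMarkovModel(structure=pm.TransitionStructure(((1, 3),)),
                                  compute_covariance=False).fit(data)
        def nll(loglam):
            p = 1 - np.exp(-np.exp(loglam) * 100.0)
            return -(11 * np.log(p) + 19 * np.log(1 - p))
        oracle = minimize_scalar(nll, bounds=(-10, 0), method="bounded").x
        fitted = est.params_.baseline_log_intensity[(1, 3)]
        assert fitted == pytest.approx(oracle, abs=1e-4)

    def test_invalid_death_mode_rejected(self):
        with pytest.raises(ValueError, match="death_mode"):
            pm.PanelMarkovModel(death_mode="sometimes").fit(None)

    def test_baseline_estimation_error_shrinks_with_sample_size(self):
        """Typical absolute error of the baseline log-intensities decreases
        from n=500 to n=2000 under the full nine-column model (consistency;
        the weakly identified Exit-hub rates are why the median, not the
        maximum, is compared)."""
        errs = {}
        for n in (500, 2000):
            cfg = pm.SimulationConfig(n_individuals=n, horizon=3600, seed=31,
                                      record_events=False)
            datasets, truth, _ = pm.generate_dataset(cfg)
            fit = pm.PanelMarkovModel(covariate_terms=pm.DESIGN_TERMS,
                                      compute_covariance=False).fit(
                                          datasets["Male"])
            err = np.abs(fit.result_.theta[:14] - truth["Male"].alpha())
            errs[n] = np.median(err)
        assert errs[2000] < errs[500]
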