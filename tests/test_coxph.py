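import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from psmcr import (
    CauseSpecificCoxPH,
    SimulationConfig,
    fit_cause_specific_cox,
    fit_transition_cox,
    log_partial_likelihood,
    nelson_aalen_baseline,
    simulate_dataset,
)
from psmcr.coxph import ConvergenceWarning

from conftest import make_dataset


def lifelines_fit(dataset, cause):
    df = dataset.to_frame().drop(columns=["id"])
    df["event"] = (df["status"] == cause).astype(int)
    return CoxPHFitter().fit(df.drop(columns=["status"]), "time", "event")


class TestFit:
    def test_symmetric_pair_gives_zero(self):
        ds = make_dataset([2.0, 2.0], [1, 1], [[0.7], [-0.7]])
        fit = fit_cause_specific_cox(ds, 1)
        assert fit.beta_hat[0] == pytest.approx(0.0, abs=1e-10)

    def test_grid_search_oracle(self):
        # explicit Breslow product for (t, status, z) = (1,1,1),(2,1,0),(3,1,1),(4,1,0)
        ds = make_dataset([1, 2, 3, 4], [1, 1, 1, 1], [[1.0], [0.0], [1.0], [0.0]])
        fit = fit_cause_specific_cox(ds, 1)
        grid = np.arange(-5, 5, 1e-4)
        e = np.exp(grid)
        lik = e / (2 * e + 2) * 1 / (e + 2) * e / (e + 1)
        assert fit.beta_hat[0] == pytest.approx(grid[np.argmax(lik)], abs=1e-4)

    @pytest.mark.parametrize("cause", [1, 2])
    def test_lifelines_agreement(self, n50_dataset, cause):
        fit = fit_cause_specific_cox(n50_dataset, cause)
        cph = lifelines_fit(n50_dataset, cause)
        np.testing.assert_allclose(fit.beta_hat, cph.params_.values, atol=1e-4)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-4)
        # partial log-likelihood evaluated at the library's own optimum
        ll = log_partial_likelihood(n50_dataset, cause, cph.params_.values)
        assert ll == pytest.approx(cph.log_likelihood_, abs=1e-8)

    def test_parameter_recovery_at_large_n(self):
        cfg = SimulationConfig(n=5000, seed=21)
        ds = simulate_dataset(cfg)
        fit = fit_cause_specific_cox(ds, 1)
        np.testing.assert_array_less(
            np.abs(fit.beta_hat - np.array(cfg.beta_cause1)), 3 * fit.se
        )

    def test_scale_equivariance(self, n50_dataset):
        fit = fit_cause_specific_cox(n50_dataset, 1, tol=1e-11)
        X = n50_dataset.X.copy()
        X[:, 0] *= 4.0
        scaled = make_dataset(n50_dataset.times, n50_dataset.statuses, X)
        fit_s = fit_cause_specific_cox(scaled, 1, tol=1e-11)
        assert fit_s.beta_hat[0] == pytest.approx(fit.beta_hat[0] / 4.0, abs=1e-8)

    def test_score_zero_and_information_pd(self, n50_dataset):
        from psmcr.coxph import _loglik_grad_hess, _prepare

        fit = fit_cause_specific_cox(n50_dataset, 1)
        events = (n50_dataset.statuses == 1).astype(int)
        t, d, Xs, ties = _prepare(n50_dataset.times, events, n50_dataset.X)
        _, grad, hess = _loglik_grad_hess(t, d, Xs, ties, fit.beta_hat)
        assert np.max(np.abs(grad)) < 1e-8
        assert np.all(np.linalg.eigvalsh(-hess) > 0)

    def test_cause1_fit_invariant_to_relabeling_cause2(self, n50_dataset):
        relabeled = n50_dataset.with_statuses(
            np.where(n50_dataset.statuses == 2, 0, n50_dataset.statuses)
        )
        a = fit_cause_specific_cox(n50_dataset, 1)
        b = fit_cause_specific_cox(relabeled, 1)
        np.testing.assert_array_equal(a.beta_hat, b.beta_hat)

    def test_maximality_of_loglik(self, n50_dataset):
        fit = fit_cause_specific_cox(n50_dataset, 1)
        ll_hat = log_partial_likelihood(n50_dataset, 1, fit.beta_hat)
        rng = np.random.default_rng(0)
        for _ in range(100):
            eps = rng.normal(size=3)
            eps *= 0.1 / np.linalg.norm(eps)
            assert ll_hat >= log_partial_likelihood(n50_dataset, 1, fit.beta_hat + eps)

    def test_loglik_at_zero_is_minus_log_risk_sets(self):
        ds = make_dataset([1, 2, 3, 4], [1, 1, 0, 1], [[0.3], [0.1], [-0.2], [0.5]])
        # risk sets at the three event times have sizes 4, 3, 1
        assert log_partial_likelihood(ds, 1, [0.0]) == pytest.approx(
            -(np.log(4) + np.log(3) + np.log(1))
        )

    def test_monotone_likelihood_flagged(self):
        ds = make_dataset([1, 2, 3, 4], [1, 1, 0, 0], [[1.0], [1.0], [0.0], [0.0]])
        with pytest.warns(ConvergenceWarning):
            fit = fit_cause_specific_cox(ds, 1, max_iter=25)
        assert not fit.converged

    def test_constant_covariate_degenerate(self):
        ds = make_dataset([1, 2], [1, 1], [[1.0], [1.0]])
        with pytest.raises(ValueError, match="constant"):
            fit_cause_specific_cox(ds, 1)

    def test_no_events_error(self):
        ds = make_dataset([1, 2], [0, 1], [[0.1], [0.4]])
        with pytest.raises(ValueError, match="no events"):
            fit_cause_specific_cox(ds, 2)


class TestBaseline:
    def test_closed_form_at_beta_zero(self):
        ds = make_dataset([1.0, 2.0], [1, 1], [[0.0], [1.0]])
        H = nelson_aalen_baseline(ds, 1, [0.0])
        assert H(1.0) == pytest.approx(0.5)
        assert H(2.0) == pytest.approx(1.5)
        assert H(0.5) == 0.0

    def test_no_events_gives_zero_function(self):
        ds = make_dataset([1.0, 2.0], [1, 1], [[0.0], [1.0]])
        H = nelson_aalen_baseline(ds, 2, [0.0])
        assert H(10.0) == 0.0

    def test_breslow_library_agreement(self, n50_dataset):
        from sksurv.linear_model.coxph import BreslowEstimator

        fit = fit_cause_specific_cox(n50_dataset, 1)
        be = BreslowEstimator().fit(
            n50_dataset.X @ fit.beta_hat, n50_dataset.statuses == 1, n50_dataset.times
        )
        # sksurv's step function extrapolates its first value below the first
        # event time, so compare on the estimator's common support
        ts = np.linspace(fit.baseline.times[0], n50_dataset.times.max(), 40)
        np.testing.assert_allclose(fit.baseline(ts), be.cum_baseline_hazard_(ts), atol=1e-8)

    def test_nondecreasing_right_continuous(self, sim_dataset):
        fit = fit_cause_specific_cox(sim_dataset, 1)
        ts = np.linspace(0, sim_dataset.times.max(), 200)
        vals = fit.baseline(ts)
        assert np.all(np.diff(vals) >= 0)
        jump_t = fit.baseline.times[0]
        assert fit.baseline(jump_t) > 0  # right-continuous at jumps


class TestTransitionCox:
    def test_reduces_to_flat_cause_specific_fit(self, n50_dataset):
        fit_flat = fit_cause_specific_cox(n50_dataset, 1)
        long = pd.DataFrame(
            {
                "id": n50_dataset.ids,
                "from_state": 2,
                "to_state": 4,
                "entry_time": 0.0,
                "exit_time": n50_dataset.times,
                "event": (n50_dataset.statuses == 1).astype(int),
                "cause": 1,
            }
        )
        for j, name in enumerate(n50_dataset.covariate_names):
            long[name] = n50_dataset.X[:, j]
        fit_long = fit_transition_cox(long, (2, 4))
        np.testing.assert_allclose(fit_long.beta_hat, fit_flat.beta_hat, atol=1e-12)

    def test_no_event_transition_errors(self):
        long = pd.DataFrame(
            {
                "id": ["a", "b"],
                "from_state": [1, 1],
                "to_state": [2, 2],
                "entry_time": [0.0, 0.0],
                "exit_time": [1.0, 2.0],
                "event": [0, 0],
                "cause": [None, None],
                "x1": [0.1, 0.5],
            }
        )
        with pytest.raises(ValueError, match="no events"):
            fit_transition_cox(long, (1, 2))


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        model = CauseSpecificCoxPH(cause=2, tol=1e-6)
        assert model.get_params()["cause"] == 2
        model.set_params(max_iter=50)
        assert model.max_iter == 50

    def test_fit_predict_shapes(self, n50_dataset):
        model = CauseSpecificCoxPH(cause=1).fit(
            n50_dataset.X, np.column_stack([n50_dataset.times, n50_dataset.statuses])
        )
        assert model.coef_.shape == (3,)
        lp = model.predict(n50_dataset.X[:5])
        np.testing.assert_allclose(lp, n50_dataset.X[:5] @ model.coef_)
        ch = model.predict_cumulative_hazard(n50_dataset.X[:2], [1.0, 2.0])
        assert ch.shape == (2, 2)
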