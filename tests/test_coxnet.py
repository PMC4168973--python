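import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from pathsurv.coxnet import (
    FeatureMatrix,
    cox_partial_loglik,
    default_lambda_grid,
    fit_cox_newton,
    fit_cox_path,
    fit_penalized_cox,
    fit_univariate_cox,
    lambda_max,
    select_lambda,
)


def breslow_loglik_oracle(beta, X, time, event):
    """Brute-force risk-set enumeration of the Breslow partial loglik."""
    eta = X @ beta
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


class TestPartialLoglik:
    def test_three_distinct_events_at_beta_zero(self):
        ll = cox_partial_loglik(np.zeros(1), np.zeros((3, 1)), np.array([1.0, 2, 3]), np.array([1, 1, 1]))
        assert ll == pytest.approx(-(np.log(3) + np.log(2) + np.log(1)), abs=1e-9)
        assert ll == pytest.approx(-1.791759, abs=1e-6)

    def test_matches_risk_set_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((6, 2))
        beta = rng.standard_normal(2)
        time = np.array([2.0, 1.0, 2.0, 3.0, 0.5, 2.0])  # tie at t=2
        event = np.array([1, 1, 1, 0, 1, 1])
        ll = cox_partial_loglik(beta, X, time, event)
        assert ll == pytest.approx(breslow_loglik_oracle(beta, X, time, event), abs=1e-12)

    def test_all_censored_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            ll = cox_partial_loglik(np.zeros(1), np.zeros((4, 1)), np.arange(1.0, 5), np.zeros(4))
        assert ll == 0.0

    def test_rank_preserving_time_transform_invariance(self, ph_data):
        X, time, event = ph_data
        beta = np.array([0.3, -0.2, 0.1])
        a = cox_partial_loglik(beta, X, time, event)
        b = cox_partial_loglik(beta, X, np.exp(time), event)  # order-preserving
        assert a == pytest.approx(b, abs=1e-10)

    def test_efron_matches_breslow_without_ties(self, ph_data):
        X, time, event = ph_data
        beta = np.array([0.3, -0.2, 0.1])
        assert cox_partial_loglik(beta, X, time, event, ties="efron") == pytest.approx(
            cox_partial_loglik(beta, X, time, event, ties="breslow"), abs=1e-10
        )


class TestNewtonAndUnivariate:
    def test_newton_matches_lifelines(self, ph_data):
        X, time, event = ph_data
        fit = fit_cox_newton(X, time, event)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = time, event
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coefficients, cph.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.covariance)), cph.standard_errors_.to_numpy(), atol=1e-4
        )

    def test_hazard_ratio_is_exp_of_coefficient(self, ph_data):
        X, time, event = ph_data
        res = fit_univariate_cox(X[:, 0], time=time, event=event, name="f")
        assert res.hazard_ratio == pytest.approx(np.exp(res.coefficient), rel=1e-12)
        assert 0 < res.p_value <= 1

    def test_no_effect_feature_gives_null_result(self):
        # identical survival experience in both halves of a binary feature
        time = np.tile(np.arange(1.0, 11), 2)
        event = np.tile(np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1]), 2)
        x = np.repeat([0.0, 1.0], 10)
        res = fit_univariate_cox(x, time=time, event=event)
        assert abs(res.coefficient) < 1e-8
        assert res.p_value > 0.99

    def test_two_group_consistency_true_hr_2(self):
        rng = np.random.default_rng(123)
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t = -np.log(rng.random(n)) / (0.2 * np.exp(np.log(2.0) * x))
        c = rng.uniform(0, 15, n)
        res = fit_univariate_cox(x, time=np.minimum(t, c), event=(t <= c).astype(int))
        assert 1.7 <= res.hazard_ratio <= 2.3

    def test_zero_variance_feature_rejected(self, ph_data):
        _, time, event = ph_data
        with pytest.raises(ValueError, match="zero variance"):
            fit_univariate_cox(np.ones(len(time)), time=time, event=event)


class TestPenalizedCox:
    def test_all_zero_at_lambda_max(self, ph_data):
        X, time, event = ph_data
        lam = lambda_max(X, time, event)
        fit = fit_penalized_cox(X, time, event, lam * 1.000001)
        assert (fit.coefficients.to_numpy() == 0.0).all()
        fit2 = fit_penalized_cox(X, time, event, lam * 2)
        assert (fit2.coefficients.to_numpy() == 0.0).all()

    def test_lambda_zero_matches_newton_mle(self, ph_data):
        X, time, event = ph_data
        fit = fit_penalized_cox(X, time, event, 0.0)
        mle = fit_cox_newton(X, time, event)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), mle.coefficients, atol=1e-4)

    def test_objective_not_worse_than_zero_vector(self, ph_data):
        X, time, event = ph_data
        for lam_frac in (0.5, 0.1, 0.01):
            lam = lam_frac * lambda_max(X, time, event)
            fit = fit_penalized_cox(X, time, event, lam)
            obj_hat = cox_partial_loglik(fit.coefficients.to_numpy(), X, time, event) - lam * np.abs(
                fit.coefficients.to_numpy()
            ).sum()
            obj_zero = cox_partial_loglik(np.zeros(X.shape[1]), X, time, event)
            assert obj_hat >= obj_zero - 1e-10

    def test_objective_trace_monotone(self, ph_data):
        X, time, event = ph_data
        fit = fit_penalized_cox(X, time, event, 0.3 * lambda_max(X, time, event))
        assert all(b >= a - 1e-10 for a, b in zip(fit.objective_trace, fit.objective_trace[1:]))

    def test_sign_flip_equivariance(self, ph_data):
        X, time, event = ph_data
        lam = 0.2 * lambda_max(X, time, event)
        fit = fit_penalized_cox(X, time, event, lam)
        Xf = X.copy()
        Xf[:, 1] *= -1
        flip = fit_penalized_cox(Xf, time, event, lam)
        np.testing.assert_allclose(flip.coefficients.iloc[1], -fit.coefficients.iloc[1], atol=1e-6)
        obj = cox_partial_loglik(fit.coefficients.to_numpy(), X, time, event)
        obj_f = cox_partial_loglik(flip.coefficients.to_numpy(), Xf, time, event)
        assert obj == pytest.approx(obj_f, abs=1e-8)

    def test_path_support_grows_toward_mle_support(self, ph_data):
        X, time, event = ph_data
        grid = default_lambda_grid(lambda_max(X, time, event), n=20)
        fits = fit_cox_path(X, time, event, grid)
        assert (fits[0].coefficients.to_numpy() == 0).all() or len(fits[0].selected_features) <= 1
        sizes = [len(f.selected_features) for f in fits]
        assert sizes[-1] >= sizes[0]


class TestSelectLambda:
    def test_single_lambda_grid_is_chosen(self, ph_data):
        X, time, event = ph_data
        sel = select_lambda(X, time, event, n_repeats=2, n_folds=3, seed=0, lambdas=np.array([0.5]))
        assert sel.chosen_lambda == 0.5

    def test_same_seed_reproduces_selection(self, ph_data):
        X, time, event = ph_data
        a = select_lambda(X, time, event, n_repeats=3, n_folds=3, seed=5)
        b = select_lambda(X, time, event, n_repeats=3, n_folds=3, seed=5)
        assert a.chosen_lambda == b.chosen_lambda
        np.testing.assert_array_equal(a.cv_loglik, b.cv_loglik)

    def test_strong_feature_retained_across_seeds(self):
        # one real effect (HR ~ 3) among 20 noise features
        kept = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n = 120
            X = rng.standard_normal((n, 21))
            t = -np.log(rng.random(n)) / (0.2 * np.exp(np.log(3.0) * X[:, 0]))
            c = rng.uniform(0, 20, n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            sel = select_lambda(X, time, event, n_repeats=3, n_folds=4, seed=seed)
            fit = fit_penalized_cox(X, time, event, sel.chosen_lambda)
            if "x0" in fit.selected_features:
                kept += 1
        assert kept >= 0.9 * n_seeds

    def test_feature_matrix_alignment(self, ph_data):
        X, time, event = ph_data
        fm = FeatureMatrix(
            pd.DataFrame(X.T, index=["a", "b", "c"], columns=[f"s{i}" for i in range(len(time))])
        )
        from pathsurv.io import SurvivalOutcome

        surv = SurvivalOutcome(
            pd.DataFrame({"time": time, "event": event}, index=[f"s{i}" for i in range(len(time))])
        )
        X2, t2, e2 = fm.align(surv)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(t2, time)
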