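"""Regression families: exact OLS, SVR vs an independent QP oracle, splits."""

import numpy as np
import pytest
from scipy.optimize import minimize

from interbrain.core import DyadDataset, HbO2Series, Montage
from interbrain.models import (
    PredictionModelSpec,
    SplitSpec,
    fit_all_channels,
    fit_ols,
    fit_svr,
    predict,
    split_series,
)
from conftest import make_config
from interbrain.simulate import generate_dyad


def svr_primal_oracle(X, y, epsilon, cost, tol=1e-12):
    """Brute-force epsilon-SVR: the primal QP with explicit slack variables.

    minimize 0.5||w||^2 + C * sum(xi_up + xi_down)
    s.t.      y - Xw - b <= eps + xi_up,  Xw + b - y <= eps + xi_down, xi >= 0

    Solved with SLSQP; independent of the production solver.
    """
    n, d = X.shape

    def unpack(z):
        return z[:d], z[d], z[d + 1 : d + 1 + n], z[d + 1 + n :]

    def obj(z):
        w, b, xu, xd = unpack(z)
        return 0.5 * w @ w + cost * (xu.sum() + xd.sum())

    def jac(z):
        w, b, xu, xd = unpack(z)
        return np.concatenate([w, [0.0], np.full(n, cost), np.full(n, cost)])

    cons = [
        {
            "type": "ineq",
            "fun": lambda z: epsilon + unpack(z)[2] - (y - X @ unpack(z)[0] - unpack(z)[1]),
        },
        {
            "type": "ineq",
            "fun": lambda z: epsilon + unpack(z)[3] - (X @ unpack(z)[0] + unpack(z)[1] - y),
        },
    ]
    bounds = [(None, None)] * (d + 1) + [(0, None)] * (2 * n)
    z0 = np.zeros(d + 1 + 2 * n)
    res = minimize(obj, z0, jac=jac, constraints=cons, bounds=bounds,
                   method="SLSQP", options={"maxiter": 2000, "ftol": tol})
    assert res.success, res.message
    w, b, *_ = unpack(res.x)
    return w, float(b)


def toy_dyad(n=200, seed=0, n_channels=4):
    rng = np.random.default_rng(seed)
    montage = Montage(
        channel_ids=tuple(range(1, n_channels + 1)),
        regions=("PFC",) * n_channels,
    )
    t = rng.standard_normal((n, n_channels))
    s = rng.standard_normal((n, n_channels))
    return DyadDataset(
        teacher=HbO2Series(t, 7.81, montage),
        student=HbO2Series(s, 7.81, montage),
    )


class TestSplit:
    @pytest.mark.parametrize("n,frac,train,test", [
        (7000, 0.5, 3500, 3500),
        (7, 0.5, 4, 3),       # ceiling rule: odd sample goes to train
        (101, 0.25, 26, 75),
    ])
    def test_boundary_arithmetic(self, n, frac, train, test):
        assert SplitSpec(frac).boundary(n) == train
        assert n - SplitSpec(frac).boundary(n) == test

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(1.0)
        with pytest.raises(ValueError):
            SplitSpec(0.0)

    def test_split_applies_same_boundary_to_both_subjects(self):
        dyad = toy_dyad(n=101)
        (t_tr, s_tr), (t_ts, s_ts) = split_series(dyad, SplitSpec(0.5))
        assert t_tr.shape[0] == s_tr.shape[0] == 51
        assert t_ts.shape[0] == s_ts.shape[0] == 50
        np.testing.assert_array_equal(
            np.vstack([t_tr, t_ts]), dyad.teacher.values)


class TestOLS:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 18))
        y = 2 * X[:, 0] - X[:, 1] + 0.5
        m = fit_ols(y, X)
        expected = np.zeros(18)
        expected[:2] = (2, -1)
        np.testing.assert_allclose(m.weights, expected, atol=1e-9)
        assert m.intercept == pytest.approx(0.5, abs=1e-9)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 18))
        y = rng.standard_normal(300)
        m = fit_ols(y, X)
        A = np.column_stack([X, np.ones(300)])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(m.weights, coef[:-1], atol=1e-9)
        assert m.intercept == pytest.approx(coef[-1], abs=1e-9)

    def test_independent_response_gives_small_weights(self):
        # orthogonalized unit-variance predictors: each w_i ~ N(0, 1/n)
        rng = np.random.default_rng(2)
        n = 3500
        q, _ = np.linalg.qr(rng.standard_normal((n, 18)))
        X = q * np.sqrt(n)
        y = rng.standard_normal(n)
        m = fit_ols(y, X)
        assert np.all(np.abs(m.weights) < 4 / np.sqrt(n))

    def test_duplicated_predictor_rejected_with_channel_names(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 5))
        X[:, 3] = X[:, 1]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(rng.standard_normal(100), X)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_ols(np.arange(5.0), np.eye(5))


class TestSVR:
    def test_constant_response_gives_zero_weights(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 6))
        m = fit_svr(np.full(60, 3.2), X, epsilon=0.1)
        np.testing.assert_allclose(m.weights, 0.0, atol=1e-9)
        assert m.intercept == pytest.approx(3.2, abs=1e-9)

    @pytest.mark.parametrize("epsilon,cost", [(0.1, 1.0), (0.25, 2.0), (0.0, 0.5)])
    def test_matches_primal_qp_oracle(self, epsilon, cost):
        # tiny dense instance solved by an independent QP
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 2))
        y = X @ np.array([1.0, -0.5]) + 0.2 * rng.standard_normal(6)
        w_ref, b_ref = svr_primal_oracle(X, y, epsilon, cost)
        m = fit_svr(y, X, epsilon=epsilon, cost=cost, standardize=False, tol=1e-9)
        np.testing.assert_allclose(m.weights, w_ref, atol=1e-6)
        assert m.intercept == pytest.approx(b_ref, abs=1e-6)

    def test_standardization_unscaling_is_algebraically_consistent(self):
        from sklearn.svm import SVR as SkSVR

        rng = np.random.default_rng(6)
        X = rng.standard_normal((150, 5)) * np.array([1, 10, 0.1, 3, 5]) + 2.0
        y = X @ rng.standard_normal(5) + 1.0 + 0.3 * rng.standard_normal(150)
        m = fit_svr(y, X, epsilon=0.1, cost=1.0, standardize=True, tol=1e-8)
        mx, sx = X.mean(0), X.std(0)
        my, sy = y.mean(), y.std()
        ref = SkSVR(kernel="linear", C=1.0, epsilon=0.1, tol=1e-8)
        ref.fit((X - mx) / sx, (y - my) / sy)
        pred_scaled_space = ref.predict((X - mx) / sx) * sy + my
        np.testing.assert_allclose(predict(m, X), pred_scaled_space, atol=1e-6)

    def test_invalid_hyperparameters_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 3))
        y = X[:, 0]
        with pytest.raises(ValueError):
            fit_svr(y, X, epsilon=-0.1)
        with pytest.raises(ValueError):
            fit_svr(y, X, cost=0.0)


class TestPredict:
    def test_zero_model_predicts_intercept(self):
        m = PredictionModelSpec("OLS", 1, np.zeros(4), 0.0)
        assert np.all(predict(m, np.random.default_rng(0).standard_normal((10, 4))) == 0)

    def test_indicator_weights_copy_teacher_channel(self):
        w = np.zeros(4)
        w[2] = 1.0
        m = PredictionModelSpec("OLS", 1, w, 0.0)
        X = np.random.default_rng(1).standard_normal((10, 4))
        np.testing.assert_array_equal(predict(m, X), X[:, 2])

    def test_prediction_on_train_matches_fitted_values(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((120, 6))
        y = rng.standard_normal(120)
        m = fit_ols(y, X)
        A = np.column_stack([X, np.ones(120)])
        fitted = A @ np.concatenate([m.weights, [m.intercept]])
        np.testing.assert_allclose(predict(m, X), fitted, atol=1e-12)

    def test_predictions_affine_in_teacher(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 3))
        m = PredictionModelSpec("OLS", 1, rng.standard_normal(3), 1.5)
        lhs = predict(m, 2.0 * X)
        rhs = 2.0 * (predict(m, X) - m.intercept) + m.intercept
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_channel_mismatch_rejected(self):
        m = PredictionModelSpec("OLS", 1, np.zeros(4), 0.0)
        with pytest.raises(ValueError, match="channels"):
            predict(m, np.zeros((10, 5)))


class TestFitAllChannels:
    def test_full_dyad_yields_36_models(self):
        dyad, _ = generate_dyad(make_config(seed=1, duration_s=120.0))
        grid = fit_all_channels(dyad)
        assert len(grid) == 36
        assert grid.skipped == []

    def test_excluded_channels_recorded_as_skips(self):
        dyad, _ = generate_dyad(make_config(seed=1, duration_s=120.0))
        grid = fit_all_channels(dyad, exclude_channels=(3, 12))
        assert len(grid) == 32
        assert len(grid.skipped) == 4
        assert {s["reason"] for s in grid.skipped} == {"qc-excluded"}

    def test_fitting_is_deterministic(self):
        dyad, _ = generate_dyad(make_config(seed=2, duration_s=120.0))
        g1 = fit_all_channels(dyad)
        g2 = fit_all_channels(dyad)
        for key in g1.models:
            np.testing.assert_array_equal(g1.models[key].weights, g2.models[key].weights)


class TestFamilyProperties:
    def test_ols_train_mse_never_exceeds_svr(self):
        # OLS is the squared-loss optimum over the same linear class
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = rng.standard_normal((150, 8))
            y = X @ rng.standard_normal(8) + rng.standard_normal(150)
            ols = fit_ols(y, X)
            svr = fit_svr(y, X)
            mse_ols = np.mean((y - predict(ols, X)) ** 2)
            mse_svr = np.mean((y - predict(svr, X)) ** 2)
            assert mse_ols <= mse_svr + 1e-12
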