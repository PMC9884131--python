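"""Tests for the penalized linear and SVR estimators and the loss plugin."""

import json

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVR as SkSVR

import optbias as ob
from optbias.models import _rbf_kernel, linear_objective, svr_objective


def test_noise_free_line_recovered_exactly():
    X = np.linspace(0, 1, 50)[:, None]
    y = 2.0 * X.ravel() + 1.0
    m = ob.fit_linear(X, y)
    assert m.W[0] == pytest.approx(2.0, abs=1e-6)
    assert m.b == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_allclose(m.predict(X), y, atol=1e-6)


@pytest.mark.parametrize("seed, d", [(0, 1), (1, 4), (2, 4)])
def test_beta_zero_reduces_to_least_squares(seed, d):
    coeffs = [2.0] if d == 1 else [1.5, -2.0, 1.0, 0.5]
    ds = ob.gen_linear(500, d, coeffs, 1.0, 0.5, seed=seed)
    m = ob.fit_linear(ds.X, ds.y)
    A = np.c_[ds.X, np.ones(ds.n)]
    ref = np.linalg.lstsq(A, ds.y, rcond=None)[0]
    fitted = np.append(m.W, m.b)
    assert np.max(np.abs(fitted - ref) / np.abs(ref)) < 1e-6


def test_fit_matches_independent_brute_force_oracle():
    """5-point univariate problem solved by grid search + generic Nelder-Mead,
    implemented here with its own objective loop."""
    X = np.arange(5, dtype=float)[:, None]
    y = np.array([0, 1, 2, 3, 10], dtype=float)
    beta = 5.0

    def oracle_cost(params):
        w, b = params
        total, pen = 0.0, 0.0
        for xi, yi in zip(X.ravel(), y):
            e = w * xi + b - yi
            total += e**2
            sgn = int(e > 0) - int(e < 0)
            pen += (-sgn + 1) * e**2  # direction="under"
        return total / 5 + 0.5 * beta * pen / 5

    grid_w = np.linspace(-5, 10, 121)
    grid_b = np.linspace(-10, 15, 121)
    best = min(((oracle_cost((w, b)), w, b) for w in grid_w for b in grid_b))
    res = minimize(oracle_cost, [best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14})
    cfg = ob.FitConfig(penalty=ob.PenaltyConfig("under", p=2, beta=beta,
                                                normalization="mean"))
    m = ob.fit_linear(X, y, cfg)
    assert m.W[0] == pytest.approx(res.x[0], abs=1e-3)
    assert m.b == pytest.approx(res.x[1], abs=1e-3)


def test_predict_examples_and_dimension_check():
    m = ob.FittedLinearModel(W=np.array([2.0]), b=1.0, converged=True,
                             n_iterations=0, final_cost=0.0)
    np.testing.assert_allclose(ob.predict(m, [[0.0], [1.0]]), [1.0, 3.0])
    m2 = ob.FittedLinearModel(W=np.zeros(2), b=5.0, converged=True,
                              n_iterations=0, final_cost=0.0)
    np.testing.assert_allclose(ob.predict(m2, np.random.rand(4, 2)), 5.0)
    with pytest.raises(ValueError):
        ob.predict(m, [[1.0, 2.0]])


def test_fit_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ob.fit_linear(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        ob.fit_linear(np.ones((3, 1)), np.ones(4))


@pytest.mark.parametrize("direction", ["over", "under"])
def test_penalized_side_count_nonincreasing_in_beta(small_linear_dataset, direction):
    ds = small_linear_dataset
    counts, psis = [], []
    for beta in [0.0, 0.01, 0.1, 1.0, 10.0]:
        cfg = ob.FitConfig(penalty=ob.PenaltyConfig(direction, 2, beta))
        m = ob.fit_linear(ds.X, ds.y, cfg)
        rep = ob.evaluate(ds.y, m.predict(ds.X))
        counts.append(rep.n_over if direction == "over" else rep.n_under)
        psis.append(ob.psi(m.predict(ds.X) - ds.y, ob.PenaltyConfig(direction, 2)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    # the penalty value itself is provably non-increasing in beta
    assert all(a >= b - 1e-9 for a, b in zip(psis, psis[1:]))


def test_fit_is_deterministic(small_linear_dataset):
    ds = small_linear_dataset
    cfg = ob.FitConfig(penalty=ob.PenaltyConfig("over", 2, 0.5))
    m1 = ob.fit_linear(ds.X, ds.y, cfg)
    m2 = ob.fit_linear(ds.X, ds.y, cfg)
    assert np.array_equal(m1.W, m2.W) and m1.b == m2.b


def test_final_cost_not_above_initial_cost(small_linear_dataset):
    ds = small_linear_dataset
    cfg = ob.FitConfig(penalty=ob.PenaltyConfig("over", 2, 1.0))
    m = ob.fit_linear(ds.X, ds.y, cfg)
    x0 = np.append(np.zeros(ds.d), np.mean(ds.y))
    assert m.final_cost <= linear_objective(x0, ds.X, ds.y, cfg) + 1e-12


def test_linear_model_json_roundtrip(tmp_path, small_linear_dataset):
    ds = small_linear_dataset
    m = ob.fit_linear(ds.X, ds.y)
    path = tmp_path / "model.json"
    m.to_json(path)
    m2 = ob.FittedLinearModel.from_json(path)
    assert np.array_equal(m.W, m2.W) and m.b == m2.b and m.converged == m2.converged


class TestSVR:
    def test_wide_tube_gives_flat_model_with_zero_insensitive_loss(self):
        X = np.linspace(0, 1, 20)[:, None]
        y = 2.0 * X.ravel() + 1.0
        cfg = ob.SVRConfig(C=1.0, epsilon=10.0, kernel="linear")
        m = ob.fit_svr(X, y, cfg)
        e = np.abs(m.predict(X) - y)
        assert np.all(e <= 10.0)  # everything inside the tube
        assert np.sum(np.maximum(0.0, e - 10.0)) == 0.0
        assert float(m.w @ m.w) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("kernel, gamma", [("linear", None), ("rbf", 0.5)])
    def test_objective_matches_reference_solver_at_beta_zero(self, kernel, gamma):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (60, 2))
        y = X @ [1.5, -2.0] + 1 + rng.normal(0, 0.3, 60)
        cfg = ob.SVRConfig(C=1.0, epsilon=0.1, kernel=kernel, gamma=gamma)
        mine = ob.fit_svr(X, y, cfg)
        sk = SkSVR(kernel=kernel, C=1.0, epsilon=0.1, tol=1e-8,
                   **({"gamma": gamma} if gamma else {})).fit(X, y)
        if kernel == "linear":
            ref = ob.FittedSVRModel(kernel="linear", w=sk.coef_.ravel(),
                                    b=sk.intercept_.item(), converged=True,
                                    n_iterations=0, final_cost=0.0)
        else:
            alpha = np.zeros(len(y))
            alpha[sk.support_] = sk.dual_coef_.ravel()
            ref = ob.FittedSVRModel(kernel="rbf", alpha=alpha, X_train=X,
                                    gamma=gamma, b=sk.intercept_.item(),
                                    converged=True, n_iterations=0, final_cost=0.0)
        obj_mine = svr_objective(mine, X, y, cfg)
        obj_ref = svr_objective(ref, X, y, cfg)
        assert abs(obj_mine - obj_ref) < 1e-3

    def test_epsilon_insensitive_term_ignores_in_tube_perturbations(self):
        from optbias.models import _eps_insensitive
        e = np.array([0.05, -0.02, 0.5, -0.8])
        base = _eps_insensitive(e, 0.1).sum()
        perturbed = e.copy()
        perturbed[0] = -0.09  # still strictly inside the tube
        assert _eps_insensitive(perturbed, 0.1).sum() == base

    def test_overestimation_rate_drops_on_degradation_data(self):
        deg = ob.gen_degradation(n_units=6, cycles_range=(128, 362),
                                 n_sensors=3, noise_sd=2.0, seed=5)
        X, y = deg.X[::4], deg.y[::4]
        X = (X - X.mean(0)) / X.std(0)
        rates = {}
        for beta in [0.0, 1.0]:
            cfg = ob.SVRConfig(C=10.0, epsilon=5.0, kernel="rbf", gamma=1 / 3,
                               max_iterations=2000,
                               penalty=ob.PenaltyConfig("over", 2, beta, "sum"))
            m = ob.fit_svr(X, y, cfg)
            rates[beta] = ob.evaluate(y, m.predict(X)).over_rate
        assert rates[1.0] < rates[0.0]

    def test_svr_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (30, 2))
        y = X.sum(axis=1) + rng.normal(0, 0.1, 30)
        for cfg in (ob.SVRConfig(kernel="linear"), ob.SVRConfig(kernel="rbf", gamma=1.0)):
            m = ob.fit_svr(X, y, cfg)
            path = tmp_path / "svr.json"
            m.to_json(path)
            m2 = ob.FittedSVRModel.from_json(path)
            np.testing.assert_allclose(m2.predict(X), m.predict(X), rtol=1e-12)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            ob.SVRConfig(C=0.0)
        with pytest.raises(ValueError):
            ob.SVRConfig(epsilon=-1.0)
        with pytest.raises(ValueError):
            ob.SVRConfig(gamma=-2.0)


class TestLossPlugin:
    def test_beta_zero_is_plain_mse(self, rng):
        value, _ = ob.make_loss_plugin(ob.PenaltyConfig(beta=0.0))
        pred, targ = rng.normal(size=20), rng.normal(size=20)
        assert value(pred, targ) == pytest.approx(np.mean((pred - targ) ** 2))

    def test_perfect_prediction_gives_zero(self):
        value, gradient = ob.make_loss_plugin(ob.PenaltyConfig("under", 2, 0.5))
        t = np.linspace(-1, 1, 10)
        assert value(t, t) == 0.0
        np.testing.assert_array_equal(gradient(t, t), np.zeros(10))

    def test_gradient_matches_finite_differences(self):
        cfg = ob.PenaltyConfig("under", 2, 0.5, "mean")
        value, gradient = ob.make_loss_plugin(cfg)
        rng = np.random.default_rng(9)
        h = 1e-6
        pred = rng.uniform(-3, 3, 20)
        targ = rng.uniform(-3, 3, 20)
        pred[np.abs(pred - targ) < 1e-4] += 1e-3
        g = gradient(pred, targ)
        for j in range(20):
            pp, pm = pred.copy(), pred.copy()
            pp[j] += h
            pm[j] -= h
            fd = (value(pp, targ) - value(pm, targ)) / (2 * h)
            assert g[j] == pytest.approx(fd, abs=1e-6)
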