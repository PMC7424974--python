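"""Epsilon-SVR: kernel, dual solver against a dense QP oracle, KKT
optimality, prediction, and hyperparameter search."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVR as SKSVR

from embryopt.dataset import FACTOR_NAMES, SurfaceConfig, generate_surface
from embryopt.metrics import r_squared
from embryopt.preprocess import fit_scaler
from embryopt.svr import (
    SVRHyperGrid,
    SVRModel,
    dual_objective,
    fit_response,
    fit_svr,
    kkt_residuals,
    rbf_kernel,
    tune_svr,
)


def brute_force_dual(X, y, C, eps, gamma):
    """Independent dense solve of the epsilon-SVR dual via SLSQP."""
    n = len(y)
    K = rbf_kernel(X, X, gamma)

    def obj(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta + eps * z.sum() - y @ beta

    def grad(z):
        g = K @ (z[:n] - z[n:])
        return np.concatenate([g + eps - y, -g + eps + y])

    res = minimize(
        obj,
        np.zeros(2 * n),
        jac=grad,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[
            {
                "type": "eq",
                "fun": lambda z: z[:n].sum() - z[n:].sum(),
                "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)]),
            }
        ],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-16},
    )
    assert res.success
    return res.x[:n] - res.x[n:]


def _random_problem(rng, n, d=3):
    X = rng.random((n, d))
    y = np.sin(3 * X[:, 0]) * 0.4 + 0.3 * X[:, 1] + rng.normal(0, 0.05, n) + 0.3
    return X, y


class TestKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.random(3)
        assert rbf_kernel(x, x, gamma=2.0) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x, z = rng.random(3), rng.random(3)
        assert rbf_kernel(x, z, 0.7) == pytest.approx(rbf_kernel(z, x, 0.7))

    def test_unit_distance_value(self):
        assert rbf_kernel(
            np.array([0.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]), 1.0
        ) == pytest.approx(np.exp(-1.0))

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            rbf_kernel(np.zeros(3), np.ones(3), 0.0)


class TestFit:
    def test_constant_targets_give_flat_zero_loss_model(self, rng):
        X = rng.random((12, 3))
        y = np.full(12, 0.4)
        model = fit_svr(X, y, C=10.0, epsilon=0.1, gamma=1.0)
        assert model.n_support == 0
        assert model.bias == pytest.approx(0.4)
        np.testing.assert_allclose(
            model.decision_function(rng.random((5, 3))), 0.4
        )

    def test_epsilon_tube_honored_at_large_C(self, rng):
        X, y = _random_problem(rng, 15)
        model = fit_svr(X, y, C=1e4, epsilon=0.1, gamma=2.0)
        resid = np.abs(model.decision_function(X) - y)
        assert resid.max() <= 0.1 + 1e-6

    def test_dual_matches_brute_force_qp_on_toy_problem(self):
        X = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.2],
                [0.0, 1.0, 0.4],
                [0.5, 0.5, 1.0],
            ]
        )
        y = np.array([0.1, 0.6, 0.3, 0.9])
        model = fit_svr(X, y, C=10.0, epsilon=0.05, gamma=1.0)
        beta = model.alpha - model.alpha_star
        beta_qp = brute_force_dual(X, y, C=10.0, eps=0.05, gamma=1.0)
        np.testing.assert_allclose(beta, beta_qp, atol=1e-5)

    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 8), (2, 10)])
    def test_dual_matches_brute_force_qp_on_random_problems(self, seed, n):
        rng = np.random.default_rng(seed)
        X, y = _random_problem(rng, n)
        for C, eps, gamma in [(5.0, 0.02, 1.0), (50.0, 0.1, 3.0)]:
            # tight solver tolerance: on a near-singular kernel a small
            # gradient gap does not yet pin the coefficients to 1e-5
            model = fit_svr(X, y, C=C, epsilon=eps, gamma=gamma, tol=1e-10)
            beta_qp = brute_force_dual(X, y, C=C, eps=eps, gamma=gamma)
            np.testing.assert_allclose(
                model.alpha - model.alpha_star, beta_qp, atol=1e-5
            )

    def test_dual_constraints_hold(self, rng):
        X, y = _random_problem(rng, 40)
        model = fit_svr(X, y, C=5.0, epsilon=0.02, gamma=2.0)
        assert np.all(model.alpha >= -1e-12) and np.all(model.alpha <= 5.0 + 1e-12)
        assert np.all(model.alpha_star >= -1e-12)
        assert abs((model.alpha - model.alpha_star).sum()) < 1e-6

    def test_kkt_residuals_below_tolerance(self, rng):
        X, y = _random_problem(rng, 50)
        for C, eps, gamma in [(1.0, 0.05, 1.0), (100.0, 0.01, 3.0)]:
            model = fit_svr(X, y, C=C, epsilon=eps, gamma=gamma)
            assert kkt_residuals(model, X, y).max() < 1e-5

    def test_dual_objective_beats_random_feasible_points(self, rng):
        X, y = _random_problem(rng, 25)
        C, eps, gamma = 5.0, 0.05, 1.5
        model = fit_svr(X, y, C=C, epsilon=eps, gamma=gamma)
        K = rbf_kernel(X, X, gamma)
        ours = dual_objective(model.alpha, model.alpha_star, K, y, eps)
        for _ in range(1000):
            a = rng.random(25) * C
            a_star = rng.permutation(a)  # equality constraint holds exactly
            assert ours >= dual_objective(a, a_star, K, y, eps) - 1e-9

    def test_sv_count_never_grows_with_epsilon(self, replicates):
        scaler = fit_scaler(replicates, list(FACTOR_NAMES) + ["emb_pct"])
        sub = replicates.iloc[::8]  # 72 rows
        X = scaler.apply_array(sub[list(FACTOR_NAMES)].to_numpy(), list(FACTOR_NAMES))
        y = scaler.apply_array(sub[["emb_pct"]].to_numpy(), ["emb_pct"]).ravel()
        counts = [
            fit_svr(X, y, C=10.0, epsilon=e, gamma=1.0).n_support
            for e in (0.01, 0.05, 0.1, 0.2, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matches_libsvm_predictions(self, replicates):
        scaler = fit_scaler(replicates, list(FACTOR_NAMES) + ["cal_pct"])
        sub = replicates.iloc[::4]  # 144 rows
        X = scaler.apply_array(sub[list(FACTOR_NAMES)].to_numpy(), list(FACTOR_NAMES))
        y = scaler.apply_array(sub[["cal_pct"]].to_numpy(), ["cal_pct"]).ravel()
        ours = fit_svr(X, y, C=10.0, epsilon=0.01, gamma=2.0)
        ref = SKSVR(C=10.0, epsilon=0.01, gamma=2.0, tol=1e-7).fit(X, y)
        np.testing.assert_allclose(
            ours.decision_function(X), ref.predict(X), atol=1e-4
        )

    def test_input_validation(self, rng):
        X, y = _random_problem(rng, 10)
        with pytest.raises(ValueError):
            fit_svr(X, y[:5], 1.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            fit_svr(X, y, -1.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            fit_svr(X, y, 1.0, 0.1, -2.0)


class TestPredict:
    def test_hand_evaluated_kernel_expansion(self, rng):
        X, y = _random_problem(rng, 8)
        model = fit_svr(X, y, C=10.0, epsilon=0.02, gamma=1.5)
        x_new = rng.random(3)
        by_hand = model.bias
        for coef, sv in zip(model.dual_coefs, model.sv_inputs):
            by_hand += coef * np.exp(-1.5 * np.sum((x_new - sv) ** 2))
        assert model.decision_function(x_new[None])[0] == pytest.approx(by_hand)

    def test_zero_coefficients_predict_bias_everywhere(self, rng):
        model = SVRModel(
            sv_inputs=np.empty((0, 3)),
            dual_coefs=np.empty(0),
            bias=0.25,
            gamma=1.0,
            C=1.0,
            epsilon=0.1,
        )
        np.testing.assert_allclose(
            model.decision_function(rng.random((6, 3))), 0.25
        )

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _random_problem(rng, 8)
        model = fit_svr(X, y, C=1.0, epsilon=0.05, gamma=1.0)
        with pytest.raises(ValueError, match="dims"):
            model.decision_function(rng.random((3, 5)))

    def test_natural_unit_round_trip_with_clipping(self, replicates):
        scaler = fit_scaler(replicates, list(FACTOR_NAMES) + ["cal_pct"])
        model = fit_response(
            replicates.iloc[::8], "cal_pct", scaler, C=10.0, epsilon=0.01, gamma=2.0
        )
        raw = model.predict(replicates.iloc[:32])
        clipped = model.predict(replicates.iloc[:32], clip=True)
        assert clipped.min() >= 0.0 and clipped.max() <= 100.0
        inside = (raw >= 0) & (raw <= 100)
        np.testing.assert_allclose(raw[inside], clipped[inside])

    def test_json_round_trip(self, rng):
        X, y = _random_problem(rng, 10)
        model = fit_svr(X, y, C=5.0, epsilon=0.05, gamma=1.0)
        again = SVRModel.from_json(model.to_json())
        Xq = rng.random((7, 3))
        np.testing.assert_allclose(
            again.decision_function(Xq), model.decision_function(Xq)
        )


class TestTune:
    def test_single_candidate_grid_returned(self, rng):
        X, y = _random_problem(rng, 30)
        grid = SVRHyperGrid(C=(7.0,), epsilon=(0.03,), gamma=(1.2,), k=3, seed=0)
        C, eps, gamma, _ = tune_svr(X, y, grid)
        assert (C, eps, gamma) == (7.0, 0.03, 1.2)

    def test_candidate_order_irrelevant(self, rng):
        X, y = _random_problem(rng, 40)
        a = SVRHyperGrid(C=(1.0, 10.0), epsilon=(0.01, 0.1), gamma=(0.5, 2.0), k=3, seed=5)
        b = SVRHyperGrid(C=(10.0, 1.0), epsilon=(0.1, 0.01), gamma=(2.0, 0.5), k=3, seed=5)
        assert tune_svr(X, y, a) == tune_svr(X, y, b)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SVRHyperGrid(C=())

    def test_noiseless_surface_recovery(self):
        cfg = SurfaceConfig(noise_sd={"cal_pct": 0.0, "emb_pct": 0.0, "num": 0.0}, n_reps=2)
        table = generate_surface(cfg, seed=0)
        scaler = fit_scaler(table, list(FACTOR_NAMES) + ["emb_pct"])
        X = scaler.apply_array(table[list(FACTOR_NAMES)].to_numpy(), list(FACTOR_NAMES))
        y = scaler.apply_array(table[["emb_pct"]].to_numpy(), ["emb_pct"]).ravel()
        C, eps, gamma, _ = tune_svr(X, y, SVRHyperGrid(seed=0))
        model = fit_response(table, "emb_pct", scaler, C, eps, gamma)
        assert r_squared(table["emb_pct"], model.predict(table)) >= 0.99
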