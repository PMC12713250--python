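"""Tests of the elastic-net solver and cross-validated selection."""

import numpy as np
import pytest

from edgevillages.enet import (
    EnetProblem,
    cross_validate,
    enet_fit,
    lambda_max,
    objective,
    select_features,
    standardize,
)


def _linear_problem(seed, n=120, p=3, beta=None):
    rng = np.random.default_rng(seed)
    X, _, _ = standardize(rng.normal(size=(n, p)))
    beta = np.asarray(beta if beta is not None else rng.normal(size=p))
    y = 0.5 + X @ beta + rng.normal(scale=0.7, size=n)
    return X, y


def _logistic_problem(seed, n=400, p=3):
    rng = np.random.default_rng(seed)
    X, _, _ = standardize(rng.normal(size=(n, p)))
    eta = -0.3 + X @ np.array([1.0, -0.8, 0.0][:p])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def _grid_search_2d(X, y, alpha, lam, span=3.0):
    """Brute-force minimizer of the linear objective over the slopes.

    With centered X the intercept is exactly ybar, so a nested 2-D zoom
    grid over the slopes finds the global optimum of the convex
    objective.
    """
    n = len(y)
    b0 = y.mean()
    center = np.zeros(2)
    width = span
    for _ in range(9):
        g1 = np.linspace(center[0] - width, center[0] + width, 41)
        g2 = np.linspace(center[1] - width, center[1] + width, 41)
        B1, B2 = np.meshgrid(g1, g2, indexing="ij")
        resid = y[:, None, None] - b0 - (X[:, 0, None, None] * B1
                                         + X[:, 1, None, None] * B2)
        loss = 0.5 * (resid ** 2).mean(axis=0)
        pen = lam * (alpha * (np.abs(B1) + np.abs(B2))
                     + 0.5 * (1 - alpha) * (B1 ** 2 + B2 ** 2))
        obj = loss + pen
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        center = np.array([g1[i], g2[j]])
        width = width / 10.0
    return b0, center


class TestEnetFit:
    def test_zero_penalty_matches_least_squares(self):
        X, y = _linear_problem(0)
        b0, beta = enet_fit(EnetProblem(X, y, alpha=0.5, lam=0.0))
        M = np.column_stack([np.ones(len(y)), X])
        ref, *_ = np.linalg.lstsq(M, y, rcond=None)
        assert abs(b0 - ref[0]) < 1e-5
        assert np.abs(beta - ref[1:]).max() < 1e-5

    def test_zero_penalty_matches_logistic_mle(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y = _logistic_problem(1)
        b0, beta = enet_fit(EnetProblem(X, y, alpha=0.5, lam=0.0,
                                        family="logistic"))
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        assert abs(b0 - ref[0]) < 1e-5
        assert np.abs(beta - ref[1:]).max() < 1e-5

    @pytest.mark.parametrize("family", ["linear", "logistic"])
    @pytest.mark.parametrize("alpha", [0.5, 1.0])
    def test_lambda_at_or_above_max_zeroes_all_slopes(self, family, alpha):
        X, y = (_linear_problem(2) if family == "linear"
                else _logistic_problem(2))
        lmax = lambda_max(X, y, alpha, family)
        _, beta = enet_fit(EnetProblem(X, y, alpha=alpha, lam=lmax * 1.001,
                                       family=family))
        assert np.all(beta == 0.0)

    def test_single_predictor_soft_threshold_vs_grid(self):
        rng = np.random.default_rng(3)
        x, _, _ = standardize(rng.normal(size=(200, 1)))
        y = 1.5 * x[:, 0] + rng.normal(size=200)
        lam = 0.4
        _, beta = enet_fit(EnetProblem(x, y, alpha=1.0, lam=lam))
        rho = (x[:, 0] @ (y - y.mean())) / len(y)
        soft = np.sign(rho) * max(abs(rho) - lam, 0.0)
        assert beta[0] == pytest.approx(soft, abs=1e-7)
        grid = np.linspace(-3, 3, 600001)
        obj = (0.5 * ((y[:, None] - y.mean() - x * grid[None, :]) ** 2
                      ).mean(axis=0) + lam * np.abs(grid))
        assert beta[0] == pytest.approx(grid[np.argmin(obj)], abs=1e-5)

    def test_two_predictor_fits_match_grid_oracle(self):
        """Dense zoom-grid search agrees with coordinate descent to 1e-6
        on 20 seeded problems."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = _linear_problem(seed, n=80, p=2)
            alpha = float(rng.choice([0.3, 0.7, 1.0]))
            lam = float(rng.uniform(0.02, 0.5))
            b0, beta = enet_fit(EnetProblem(X, y, alpha=alpha, lam=lam))
            b0_ref, beta_ref = _grid_search_2d(X, y, alpha, lam)
            assert np.abs(beta - beta_ref).max() < 1e-6
            assert abs(b0 - b0_ref) < 1e-6

    def test_objective_never_above_zero_vector(self):
        for seed in range(10):
            X, y = _linear_problem(seed)
            prob = EnetProblem(X, y, alpha=0.6, lam=0.1)
            b0, beta = enet_fit(prob)
            assert objective(prob, b0, beta) <= objective(
                prob, y.mean(), np.zeros(X.shape[1])) + 1e-12

    def test_logistic_fit_is_local_minimum(self):
        X, y = _logistic_problem(4)
        prob = EnetProblem(X, y, alpha=0.5, lam=0.05, family="logistic")
        b0, beta = enet_fit(prob)
        base = objective(prob, b0, beta)
        rng = np.random.default_rng(0)
        for _ in range(200):
            d0, d = rng.normal(scale=1e-3), rng.normal(scale=1e-3,
                                                       size=len(beta))
            assert objective(prob, b0 + d0, beta + d) >= base - 1e-12

    def test_matches_sklearn_elastic_net(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        for seed in range(5):
            X, y = _linear_problem(seed, n=150, p=4)
            ref = sklearn_lm.ElasticNet(alpha=0.2, l1_ratio=0.7,
                                        tol=1e-12, max_iter=200000)
            ref.fit(X, y)
            b0, beta = enet_fit(EnetProblem(X, y, alpha=0.7, lam=0.2))
            assert np.abs(beta - ref.coef_).max() < 1e-4
            assert abs(b0 - ref.intercept_) < 1e-4

    def test_path_jumps_shrink_under_grid_refinement(self):
        X, y = _linear_problem(6, n=150, p=5)
        from edgevillages.enet import _path_fit
        lmax = lambda_max(X, y, 1.0, "linear")

        def max_jump(n_lambda):
            lams = lmax * np.geomspace(1.0, 1e-3, n_lambda)
            path = _path_fit(X, y, 1.0, lams, "linear")
            betas = np.array([b for _, b in path])
            return np.abs(np.diff(betas, axis=0)).max()

        assert max_jump(100) <= max_jump(25) + 1e-12


class TestCrossValidate:
    def test_row_count_is_grid_size(self):
        X, y = _logistic_problem(5, n=120)
        table = cross_validate(X, y, folds=5, alphas=(1.0, 0.5),
                               n_lambda=12, seed=0)
        assert len(table) == 2 * 12

    def test_selection_minimizes_cv_deviance_with_larger_lambda_ties(self):
        X, y = _linear_problem(7, n=100, p=4)
        table = cross_validate(X, y, family="linear", folds=5,
                               alphas=(1.0, 0.5), n_lambda=15, seed=1)
        best_dev = table["cv_mean_deviance"].min()
        ties = table[table["cv_mean_deviance"] == best_dev]
        assert table.attrs["selected_lambda"] == ties["lambda"].max()

    def test_seeded_folds_reproducible(self):
        X, y = _logistic_problem(8, n=120)
        a = cross_validate(X, y, folds=5, alphas=(1.0,), n_lambda=8, seed=3)
        b = cross_validate(X, y, folds=5, alphas=(1.0,), n_lambda=8, seed=3)
        assert a.equals(b)

    def test_pure_noise_selection_stays_sparse(self):
        """With no true signal (p = 12, n = 200, binary noise response)
        the CV-selected model keeps <= 2 nonzero slopes in >= 80% of 50
        seeded replicates."""
        sparse = 0
        for rep in range(50):
            rng = np.random.default_rng(3000 + rep)
            X = rng.normal(size=(200, 12))
            y = (rng.random(200) < 0.5).astype(float)
            table = cross_validate(X, y, family="logistic", folds=10,
                                   alphas=(1.0, 0.5), n_lambda=30, seed=rep)
            sel = select_features(table, X, y)
            sparse += len(sel) <= 2
        assert sparse >= 40

    def test_too_few_samples_rejected(self):
        X, y = _linear_problem(9, n=8, p=2)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, family="linear", folds=10)


class TestSelectFeatures:
    def test_strong_signal_variables_recovered(self):
        rng = np.random.default_rng(10)
        n, p = 300, 8
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:3] = [1.0, -1.0, 1.0]
        y = X @ beta + rng.normal(scale=0.8, size=n)
        names = [f"ind{j}" for j in range(p)]
        table = cross_validate(X, y, family="linear", folds=10,
                               alphas=(1.0, 0.5), n_lambda=25, seed=0,
                               names=names)
        sel = select_features(table, X, y, names=names,
                              groups={"ind0": "active"})
        assert {"ind0", "ind1", "ind2"} <= set(sel["indicator"])
        assert sel.set_index("indicator").loc["ind0", "group"] == "active"

    def test_lambda_max_forces_empty_selection_with_warning(self, caplog):
        X, y = _linear_problem(11, n=100, p=3)
        table = cross_validate(X, y, family="linear", folds=5,
                               alphas=(1.0,), n_lambda=5, seed=0)
        table.attrs["selected_lambda"] = 10 * lambda_max(
            standardize(X)[0], y, 1.0)
        table.attrs["selected_alpha"] = 1.0
        with caplog.at_level("WARNING"):
            sel = select_features(table, X, y)
        assert sel.empty
        assert "no indicators" in caplog.text
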