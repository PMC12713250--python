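"""Tests of conditional/mixed logit estimation and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from edgevillages import (
    ChoiceDataset,
    LogitFit,
    assemble_indicators,
    build_choice_dataset,
    fit_logit,
    lr_test,
    predict_probabilities,
    vif,
    wald_test,
)


def simulate_dataset(seed, n=800, gamma=(-1.0, 0.5), asc=0.3,
                     beta_x=(0.8,)):
    """Simulate a binary-menu dataset from the logit choice process."""
    rng = np.random.default_rng(seed)
    k_z, k_x = len(gamma), len(beta_x)
    z = rng.normal(size=(n, 2, k_z))
    x = rng.normal(size=(n, k_x))
    dz = z[:, 1, :] - z[:, 0, :]
    eta = dz @ np.asarray(gamma) + asc + x @ np.asarray(beta_x)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return ChoiceDataset(
        case_ids=[f"c{i}" for i in range(n)], z=z,
        z_names=[f"z{j}" for j in range(k_z)], x=x,
        x_names=[f"x{j}" for j in range(k_x)], choice=y, base=0)


def intercept_only_dataset(n1, n0):
    n = n1 + n0
    return ChoiceDataset(
        case_ids=[f"c{i}" for i in range(n)],
        z=np.zeros((n, 2, 0)), z_names=[],
        x=np.zeros((n, 0)), x_names=[],
        choice=np.array([1] * n1 + [0] * n0), base=0)


class TestBuildChoiceDataset:
    def test_cases_and_alternatives(self, default_chain):
        table = assemble_indicators(default_chain["county"],
                                    network=default_chain["network"])
        et = default_chain["edge_table"]
        observed = et["cross_township_share"].notna()
        ds = build_choice_dataset(table.loc[observed], et)
        assert ds.z.shape == (observed.sum(), 2, 2)
        assert len(ds.case_ids) == observed.sum()
        assert set(np.unique(ds.choice)) <= {0, 1}

    def test_identical_alternatives_detected(self):
        n = 20
        rng = np.random.default_rng(0)
        z = np.repeat(rng.normal(size=(n, 1, 1)), 2, axis=1)
        ds = ChoiceDataset(case_ids=[f"c{i}" for i in range(n)], z=z,
                           z_names=["z0"], x=rng.normal(size=(n, 1)),
                           x_names=["x0"],
                           choice=rng.integers(0, 2, n), base=0)
        with pytest.raises(ValueError, match="unidentified"):
            fit_logit(ds)

    def test_base_alternative_swap_flips_case_specific_signs(self):
        ds0 = simulate_dataset(3)
        ds1 = ChoiceDataset(case_ids=ds0.case_ids, z=ds0.z,
                            z_names=ds0.z_names, x=ds0.x,
                            x_names=ds0.x_names, choice=ds0.choice, base=1)
        f0, f1 = fit_logit(ds0), fit_logit(ds1)
        assert f0.loglik == pytest.approx(f1.loglik, abs=1e-8)
        for zn in ds0.z_names:
            assert f0.params[zn] == pytest.approx(f1.params[zn], abs=1e-6)
        for cn in ["ASC"] + ds0.x_names:
            assert f0.params[cn] == pytest.approx(-f1.params[cn], abs=1e-6)


class TestFitLogit:
    def test_intercept_only_closed_form(self):
        ds = intercept_only_dataset(30, 70)
        fit = fit_logit(ds)
        assert fit.params["ASC"] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        ds = simulate_dataset(4)
        fit = fit_logit(ds)
        M, y, names = ds.design()
        ref = sm.Logit(y, M).fit(disp=0)
        assert np.abs(fit.params.to_numpy() - ref.params).max() < 1e-5
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_mle_beats_perturbations(self):
        ds = simulate_dataset(5, n=400)
        fit = fit_logit(ds)
        M, y, _ = ds.design()

        def loglik(theta):
            eta = M @ theta
            return -(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0)
                     - y * eta).sum()

        rng = np.random.default_rng(0)
        theta_hat = fit.params.to_numpy()
        for _ in range(100):
            assert loglik(theta_hat + rng.normal(scale=0.05,
                                                 size=len(theta_hat))) \
                <= fit.loglik + 1e-10

    def test_estimates_within_sampling_error(self):
        truth = {"z0": -1.0, "z1": 0.5, "ASC": 0.3, "x0": 0.8}
        fit = fit_logit(simulate_dataset(6, n=4000))
        for name, val in truth.items():
            assert abs(fit.params[name] - val) < 3 * fit.se[name]

    def test_msl_with_zero_variance_equals_mle(self):
        ds = simulate_dataset(7, n=300)
        exact = fit_logit(ds)
        msl = fit_logit(ds, random_spec={"z0": 0.0}, n_draws=40, seed=1,
                        estimate_sd=False)
        common = exact.params.index
        assert np.abs(msl.params[common] - exact.params).max() < 1e-4
        assert msl.loglik == pytest.approx(exact.loglik, abs=1e-4)

    def test_msl_estimates_mixing_sd(self):
        ds = simulate_dataset(8, n=500)
        fit = fit_logit(ds, random_spec={"z0": 0.5}, n_draws=50, seed=2)
        assert "sd_z0" in fit.params.index
        assert fit.loglik >= fit_logit(ds).loglik - 1e-6


class TestPredictProbabilities:
    def test_rows_sum_to_one_and_closed_forms(self):
        ds = intercept_only_dataset(50, 50)
        fit = LogitFit(params=pd.Series([np.log(3.0)], index=["ASC"]),
                       cov=pd.DataFrame([[1.0]], index=["ASC"],
                                        columns=["ASC"]),
                       loglik=0.0, dataset=ds)
        probs = predict_probabilities(fit, ds)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert probs.iloc[0]["cross-region"] == pytest.approx(0.75)
        fit0 = LogitFit(params=pd.Series([0.0], index=["ASC"]),
                        cov=pd.DataFrame([[1.0]], index=["ASC"],
                                         columns=["ASC"]),
                        loglik=0.0, dataset=ds)
        assert predict_probabilities(fit0, ds).iloc[0].tolist() == [0.5, 0.5]

    def test_common_utility_shift_leaves_probabilities_unchanged(self):
        ds = simulate_dataset(9, n=200)
        fit = fit_logit(ds)
        shifted = ChoiceDataset(case_ids=ds.case_ids, z=ds.z + 5.0,
                                z_names=ds.z_names, x=ds.x,
                                x_names=ds.x_names, choice=ds.choice,
                                base=ds.base)
        pd.testing.assert_frame_equal(predict_probabilities(fit, ds),
                                      predict_probabilities(fit, shifted))


class TestDiagnostics:
    def test_wald_zero_coefficients(self):
        ds = intercept_only_dataset(10, 10)
        fit = LogitFit(params=pd.Series([0.0, 0.0], index=["z0", "ASC"]),
                       cov=pd.DataFrame(np.eye(2), index=["z0", "ASC"],
                                        columns=["z0", "ASC"]),
                       loglik=0.0, dataset=ds)
        chi2, df, p = wald_test(fit)
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_wald_scalar_equals_z_squared(self):
        ds = simulate_dataset(10, n=500, gamma=(-1.0,), beta_x=())
        fit = fit_logit(ds)
        chi2, df, _ = wald_test(fit, drop=("ASC",))
        assert df == 1
        assert chi2 == pytest.approx(fit.zvalues["z0"] ** 2, rel=1e-10)

    def test_wald_matches_brute_force_quadratic_form(self):
        ds = simulate_dataset(11)
        fit = fit_logit(ds)
        chi2, df, _ = wald_test(fit)
        slopes = [n for n in fit.params.index if n != "ASC"]
        b = fit.params[slopes].to_numpy()
        V = fit.cov.loc[slopes, slopes].to_numpy()
        assert chi2 == pytest.approx(b @ np.linalg.inv(V) @ b, rel=1e-8)
        assert df == len(slopes)

    def test_lr_identical_models(self):
        ds = simulate_dataset(12)
        fit = fit_logit(ds)
        chi2, df, p = lr_test(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_lr_single_dropped_parameter(self):
        ds = simulate_dataset(13)
        reduced = ChoiceDataset(case_ids=ds.case_ids, z=ds.z,
                                z_names=ds.z_names,
                                x=np.zeros((len(ds.case_ids), 0)),
                                x_names=[], choice=ds.choice, base=ds.base)
        chi2, df, p = lr_test(fit_logit(ds), fit_logit(reduced))
        assert df == 1 and chi2 >= 0.0 and 0.0 <= p <= 1.0

    def test_lr_rejects_non_nested_ordering(self):
        ds = simulate_dataset(14)
        fit = fit_logit(ds)
        worse = LogitFit(params=fit.params, cov=fit.cov,
                         loglik=fit.loglik - 5.0, dataset=ds)
        with pytest.raises(ValueError, match="nested"):
            lr_test(worse, fit)


class TestVif:
    def test_orthogonal_columns_all_one(self):
        n = 64
        X = np.column_stack([np.tile([1.0, -1.0], n // 2),
                             np.repeat([1.0, -1.0], n // 2)])
        assert np.allclose(vif(X).to_numpy(), 1.0)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        v = vif(np.column_stack([x, x, rng.normal(size=50)]))
        assert np.isinf(v.iloc[0]) and np.isinf(v.iloc[1])

    def test_exact_correlation_point_six(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)          # orthogonalize
        b /= b.std()
        x2 = 0.6 * a + np.sqrt(1 - 0.36) * b
        v = vif(np.column_stack([a, x2]))
        assert v.iloc[0] == pytest.approx(1.5625, rel=1e-10)
        assert v.iloc[1] == pytest.approx(1.5625, rel=1e-10)

    def test_shape_requirements(self):
        with pytest.raises(ValueError, match="2 columns"):
            vif(np.ones((10, 1)))
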