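"""Conditional / mixed logit estimation of cross-region care choice.

Random-utility setup: the utility of case (village) i choosing
alternative j in {non-cross-region, cross-region} is U_ij = V_ij + e_ij
with i.i.d. Gumbel errors, so choice probabilities are multinomial
logit.  Observable utility carries alternative-specific covariates
z'_ij (travel time, facility capacity, optionally a cross-county flag)
with generic coefficients, while case-specific covariates x'_i
(cohesion, village class, population, ethnic share) and the
alternative-specific constant (ASC) enter the non-base alternative
only.

With two alternatives the conditional logit collapses to a binary logit
on covariate differences; the exact MLE is found by Newton-Raphson on
the analytic gradient.  Normal mixing over selected coefficients is
available through maximum simulated likelihood with scrambled Halton
draws.  Wald, likelihood-ratio and VIF diagnostics mirror standard
discrete-choice reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from scipy.stats import qmc

__all__ = [
    "ChoiceDataset",
    "LogitFit",
    "build_choice_dataset",
    "fit_logit",
    "predict_probabilities",
    "wald_test",
    "lr_test",
    "vif",
]

ALTERNATIVES = ("non-cross-region", "cross-region")


@dataclass
class ChoiceDataset:
    """Binary-menu choice data in difference form.

    ``z`` has shape (n, 2, k_z): alternative-specific covariates for the
    two alternatives in the order of :data:`ALTERNATIVES`; ``x`` has
    shape (n, k_x): case-specific covariates.  ``choice`` holds the
    chosen alternative index (0/1).  ``base`` is the index of the base
    alternative whose ASC and case-specific terms are normalized to 0.
    """

    case_ids: list[str]
    z: np.ndarray
    z_names: list[str]
    x: np.ndarray
    x_names: list[str]
    choice: np.ndarray
    base: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.choice = np.asarray(self.choice, dtype=int)
        n = len(self.case_ids)
        if self.z.shape[:2] != (n, 2) or len(self.x) != n or len(self.choice) != n:
            raise ValueError("inconsistent choice-dataset shapes")
        if not set(np.unique(self.choice)) <= {0, 1}:
            raise ValueError("choice must index one of the 2 alternatives")
        if self.base not in (0, 1):
            raise ValueError("base alternative index must be 0 or 1")

    @property
    def nonbase(self) -> int:
        return 1 - self.base

    def design(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(M, y, names): binary-logit design for the non-base alternative.

        Columns are the z differences (non-base minus base), the ASC
        column of ones, then the case-specific covariates; y indicates
        choosing the non-base alternative.
        """
        dz = self.z[:, self.nonbase, :] - self.z[:, self.base, :]
        M = np.column_stack([dz, np.ones(len(dz)), self.x])
        names = list(self.z_names) + ["ASC"] + list(self.x_names)
        y = (self.choice == self.nonbase).astype(float)
        return M, y, names


@dataclass
class LogitFit:
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    dataset: ChoiceDataset = field(repr=False)
    n_draws: int = 0
    seed: int = 0
    random_spec: dict = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def summary(self) -> pd.DataFrame:
        alt_specific = set(self.dataset.z_names)
        chi2, df, p = wald_test(self)
        out = pd.DataFrame({
            "variable_type": ["alternative-specific" if n in alt_specific
                              else "individual-specific"
                              for n in self.params.index],
            "coefficient": self.params,
            "std_error": self.se,
            "p_value": self.pvalues,
        })
        out.attrs.update({"wald_chi2": chi2, "wald_df": df, "wald_p": p,
                          "loglik": self.loglik, "n_draws": self.n_draws})
        return out


def build_choice_dataset(indicator_table: pd.DataFrame,
                         edge_table: pd.DataFrame,
                         base_alternative: str = "non-cross-region",
                         z_names=("travel_time", "capacity"),
                         x_names=("cohesion", "village_class",
                                  "population", "ethnic_share")
                         ) -> ChoiceDataset:
    """Assemble the binary choice dataset from the indicator table.

    The local (non-cross-region) alternative carries each village's
    own-township facility attributes; the cross-region alternative
    carries the ``*_cross`` columns.  The observed choice is
    cross-region when the village's main outflow destination lies
    outside its administrative township.
    """
    if base_alternative not in ALTERNATIVES:
        raise ValueError(f"base_alternative must be one of {ALTERNATIVES}")
    idx = indicator_table.index
    missing = [c for c in list(z_names) + [f"{c}_cross" for c in z_names]
               + list(x_names) if c not in indicator_table.columns]
    if missing:
        raise ValueError(f"indicator table lacks columns {missing}")
    z_local = indicator_table[list(z_names)].to_numpy(float)
    z_cross = indicator_table[[f"{c}_cross" for c in z_names]].to_numpy(float)
    z = np.stack([z_local, z_cross], axis=1)      # order = ALTERNATIVES
    x = indicator_table[list(x_names)].to_numpy(float)
    if np.isnan(z).any() or np.isnan(x).any():
        raise ValueError("choice dataset has missing covariates")

    et = edge_table.reindex(idx)
    chose_cross = (et["cross_township_share"] > 0.5)
    if chose_cross.isna().any():
        bad = list(idx[chose_cross.isna()])
        raise ValueError(f"villages lack observed flows for the choice "
                         f"outcome: {bad}")
    choice = chose_cross.to_numpy(bool).astype(int)   # 1 = cross-region

    ds = ChoiceDataset(
        case_ids=list(idx), z=z, z_names=list(z_names),
        x=x, x_names=list(x_names), choice=choice,
        base=ALTERNATIVES.index(base_alternative),
    )
    _check_identification(ds)
    return ds


def _check_identification(ds: ChoiceDataset) -> None:
    M, _, names = ds.design()
    dz = M[:, :len(ds.z_names)]
    degenerate = [ds.z_names[j] for j in range(dz.shape[1])
                  if np.allclose(dz[:, j], dz[0, j])]
    if degenerate:
        raise ValueError(
            "alternative-specific covariates do not vary between the two "
            f"alternatives; their coefficients are unidentified: {degenerate}")
    if np.linalg.matrix_rank(M) < M.shape[1]:
        _, r = np.linalg.qr(M)
        bad = [names[j] for j in range(M.shape[1])
               if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def _loglik_grad_hess(theta, M, y):
    eta = M @ theta
    prob = expit(eta)
    ll = -(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta).sum()
    grad = M.T @ (y - prob)
    w = prob * (1.0 - prob)
    hess = -(M * w[:, None]).T @ M
    return ll, grad, hess


def fit_logit(dataset: ChoiceDataset, random_spec: dict | None = None,
              n_draws: int = 500, seed: int = 0,
              estimate_sd: bool = True) -> LogitFit:
    """Estimate the choice model by (simulated) maximum likelihood.

    With ``random_spec`` empty the exact conditional-logit MLE is found
    by Newton-Raphson (gradient norm < 1e-6 at the optimum) and the
    covariance is the inverse observed information.  ``random_spec``
    maps coefficient names to starting standard deviations of a normal
    mixing distribution, integrated by scrambled Halton draws (bases 2,
    3, ..., first 50 points dropped); with ``estimate_sd=False`` the
    standard deviations stay fixed.
    """
    M, y, names = dataset.design()
    _check_identification(dataset)
    if not random_spec:
        theta = np.zeros(M.shape[1])
        for it in range(100):
            ll, grad, hess = _loglik_grad_hess(theta, M, y)
            if np.linalg.norm(grad) < 1e-9:
                break
            try:
                step = np.linalg.solve(hess, -grad)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError("singular Hessian during Newton "
                                   "iteration") from exc
            # halving line search on the log-likelihood
            scale = 1.0
            for _ in range(40):
                ll_new, _, _ = _loglik_grad_hess(theta + scale * step, M, y)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            theta = theta + scale * step
        else:
            raise RuntimeError(
                f"Newton-Raphson did not converge; |grad| = "
                f"{np.linalg.norm(grad):.3e}")
        ll, grad, hess = _loglik_grad_hess(theta, M, y)
        cov = np.linalg.inv(-hess)
        return LogitFit(params=pd.Series(theta, index=names),
                        cov=pd.DataFrame(cov, index=names, columns=names),
                        loglik=float(ll), dataset=dataset, n_draws=0,
                        seed=seed)
    return _fit_msl(dataset, M, y, names, dict(random_spec), n_draws, seed,
                    estimate_sd)


def _halton_normal(n_cases: int, n_draws: int, dim: int, seed: int) -> np.ndarray:
    sampler = qmc.Halton(d=dim, scramble=True, seed=seed)
    sampler.fast_forward(50)
    u = sampler.random(n_cases * n_draws)
    return stats.norm.ppf(u).reshape(n_cases, n_draws, dim)


def _fit_msl(dataset, M, y, names, random_spec, n_draws, seed, estimate_sd):
    rand_idx = [names.index(nm) for nm in random_spec]
    if not rand_idx:
        raise ValueError("random_spec names not found in the design")
    draws = _halton_normal(len(y), n_draws, len(rand_idx), seed)

    def sim_loglik(full):
        mean = full[:len(names)]
        sds = np.abs(full[len(names):]) if estimate_sd else np.asarray(
            [random_spec[nm] for nm in random_spec])
        eta_fixed = M @ mean
        dev = np.einsum("nrk,nk->nr", draws * sds[None, None, :],
                        M[:, rand_idx])
        eta = eta_fixed[:, None] + dev
        p1 = expit(eta)
        pc = np.where(y[:, None] == 1.0, p1, 1.0 - p1).mean(axis=1)
        return float(np.log(np.clip(pc, 1e-300, None)).sum())

    start = np.zeros(len(names) + (len(rand_idx) if estimate_sd else 0))
    if estimate_sd:
        start[len(names):] = [max(random_spec[nm], 0.1) for nm in random_spec]
    res = optimize.minimize(lambda t: -sim_loglik(t), start, method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-6})
    mean = res.x[:len(names)]
    all_names = list(names)
    if estimate_sd:
        all_names += [f"sd_{nm}" for nm in random_spec]
    hess = _numeric_hessian(lambda t: -sim_loglik(t), res.x)
    try:
        cov_full = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(hess)
    params = pd.Series(np.concatenate([mean, res.x[len(names):]]),
                       index=all_names)
    cov = pd.DataFrame(cov_full, index=all_names, columns=all_names)
    return LogitFit(params=params, cov=cov, loglik=float(-res.fun),
                    dataset=dataset, n_draws=n_draws, seed=seed,
                    random_spec=random_spec)


def _numeric_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            h[i, j] = h[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps * eps)
    return h


def predict_probabilities(fit: LogitFit, dataset: ChoiceDataset) -> pd.DataFrame:
    """Per-case probabilities of the two alternatives (rows sum to 1)."""
    M, _, names = dataset.design()
    if list(fit.params.index[:len(names)]) != names:
        raise ValueError("fit and dataset schemas are incompatible")
    eta = M @ fit.params.to_numpy()[:len(names)]
    p_nonbase = expit(eta)
    probs = np.empty((len(eta), 2))
    probs[:, dataset.nonbase] = p_nonbase
    probs[:, dataset.base] = 1.0 - p_nonbase
    return pd.DataFrame(probs, index=dataset.case_ids, columns=ALTERNATIVES)


def wald_test(fit: LogitFit, drop: tuple = ("ASC",)) -> tuple[float, int, float]:
    """Joint Wald test that all slope parameters are zero.

    chi2 = b' V^-1 b over the slope subvector (ASC and any mixing
    standard deviations excluded); df = number of slopes.
    """
    slope_names = [n for n in fit.params.index
                   if n not in drop and not n.startswith("sd_")]
    b = fit.params[slope_names].to_numpy()
    V = fit.cov.loc[slope_names, slope_names].to_numpy()
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance in Wald test") from exc
    df = len(slope_names)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def lr_test(fit_full: LogitFit, fit_reduced: LogitFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested reduced model."""
    df = len(fit_full.params) - len(fit_reduced.params)
    if df < 0:
        raise ValueError("reduced model has more parameters than the full one")
    chi2 = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if chi2 < -1e-8:
        raise ValueError(
            "full-model log-likelihood below the reduced model's: models "
            "are not nested or the optimizer failed")
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def vif(design) -> pd.Series:
    """Variance inflation factors, VIF_k = 1 / (1 - R^2_k).

    R^2_k comes from regressing column k on the remaining columns (with
    intercept).  Perfectly collinear columns report ``inf``.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 columns")
    if n <= p:
        raise ValueError("VIF needs more rows than columns")
    out = []
    for k in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        yk = X[:, k]
        coef, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ coef
        tss = ((yk - yk.mean()) ** 2).sum()
        if tss == 0:
            out.append(np.inf)
            continue
        r2 = 1.0 - (resid ** 2).sum() / tss
        out.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.Series(out, index=names, name="vif")
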