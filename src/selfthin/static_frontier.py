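"""Static site-level frontier fits on (ln dg, ln N) plot data.

Three strategies estimate the self-thinning relationship ln N = b0 + b1 ln dg
from single-occasion (static) plot measurements, each handling the one-sided
nature of frontier data differently:

* **LME** — Gaussian linear mixed model with plot random effects on both
  coefficients; the frontier is obtained downstream by shifting the intercept
  to the upper bound of its 95% confidence interval.
* **LQMM** — linear quantile mixed model: the conditional tau-quantile
  (default tau = 0.95) of ln N, fitted by maximum likelihood under an
  asymmetric Laplace (ALD) residual kernel with a Gaussian plot random
  intercept integrated out by Gauss-Hermite quadrature. Maximizing the ALD
  likelihood is equivalent to minimizing the pinball (check) loss, so with
  the random-effect variance pinned at zero this reduces exactly to classical
  quantile regression.
* **SFMM** — stochastic frontier regression with composed error V - U
  (V Gaussian noise, U half-normal one-sided shortfall from the frontier)
  and a Gaussian plot random intercept; the marginal composed-error density
  is (2/sigma) phi(eps/sigma) Phi(-eps*lambda/sigma) with
  sigma^2 = sigma_u^2 + sigma_v^2 and lambda = sigma_u/sigma_v.

All models are fitted by maximum likelihood (not REML) so their BICs are
comparable across strategies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from ._optim import (
    ConvergenceError,
    gauss_hermite,
    hessian_se,
    logsumexp_weighted,
    maximize,
    opg_se,
)

__all__ = [
    "LMEFit",
    "QuantileFit",
    "FrontierFit",
    "fit_lme_reineke",
    "fit_lqmm",
    "select_quantile",
    "fit_sfmm",
    "fit_ald_mixed",
]


# --------------------------------------------------------------------------
# fit result containers
# --------------------------------------------------------------------------

@dataclass
class LMEFit:
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    var_u0: float
    var_u1: float
    var_e: float
    corr_u: float
    loglik: float
    bic: float
    plot_effects: dict[str, tuple[float, float]]
    random_slope: bool = True


@dataclass
class QuantileFit:
    tau: float
    beta0_tau: float
    beta1_tau: float
    se_beta0: float
    se_beta1: float
    var_u0: float
    sigma_ala: float
    loglik: float
    plot_effects: dict[str, float] = field(default_factory=dict)
    bic: float = float("nan")
    # aliases used by the line-derivation layer
    @property
    def beta0(self) -> float:
        return self.beta0_tau

    @property
    def beta1(self) -> float:
        return self.beta1_tau


@dataclass
class FrontierFit:
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    sigma_v: float
    sigma_u: float
    var_u0re: float
    loglik: float
    bic: float = float("nan")
    plot_effects: dict[str, float] = field(default_factory=dict)

    @property
    def lam(self) -> float:
        return self.sigma_u / self.sigma_v


def _design(plots: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = np.log(plots["n_ha"].to_numpy(dtype=float))
    x = np.log(plots["dg_cm"].to_numpy(dtype=float))
    groups = plots["plot_id"].to_numpy()
    return y, x, groups


# --------------------------------------------------------------------------
# S-P-LME
# --------------------------------------------------------------------------

def fit_lme_reineke(plots: pd.DataFrame, reml: bool = False) -> LMEFit:
    """Reineke model with plot random effects on intercept and slope.

    ln N_ij = (b0 + u0i) + (b1 + u1i) ln dg_ij + e_ij, (u0, u1) bivariate
    Gaussian. Falls back to a random intercept (with a warning) when the
    random-slope covariance is singular, which is unavoidable when every plot
    contributes a single observation.
    """
    y, x, groups = _design(plots)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct dg values")
    if np.unique(groups).size < 2:
        raise ValueError("need at least 2 plots")
    exog = sm.add_constant(x)
    df = pd.DataFrame({"y": y, "lndg": x, "g": groups})
    singletons = df.groupby("g").size().max() == 1

    random_slope = not singletons
    fit = None
    if random_slope:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(y, exog, groups=groups, exog_re=exog)
                fit = model.fit(reml=reml, method=["lbfgs", "powell"])
            cov_re = np.asarray(fit.cov_re)
            if not np.all(np.linalg.eigvalsh(cov_re) > 1e-10):
                raise np.linalg.LinAlgError("singular random-effects covariance")
            if not np.all(np.isfinite(fit.bse_fe[:2])):
                raise np.linalg.LinAlgError("fixed-effect SEs undefined at the boundary")
        except Exception:
            fit = None
            random_slope = False
            warnings.warn("random-slope covariance singular; refitting with random intercept only")
    if fit is None:
        if singletons:
            warnings.warn("one observation per plot: random effects shrink to zero; "
                          "fitting random intercept only")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(y, exog, groups=groups)
                fit = model.fit(reml=reml, method=["lbfgs", "powell"])
        except np.linalg.LinAlgError:
            # degenerate (e.g. noise-free) data: random effects vanish -> OLS
            warnings.warn("mixed fit degenerate; falling back to OLS with zero variance components")
            ols = sm.OLS(y, exog).fit()
            return LMEFit(
                beta0=float(ols.params[0]), beta1=float(ols.params[1]),
                se_beta0=float(ols.bse[0]), se_beta1=float(ols.bse[1]),
                var_u0=0.0, var_u1=0.0, var_e=float(ols.scale), corr_u=0.0,
                loglik=float(ols.llf), bic=float(ols.bic),
                plot_effects={str(g): (0.0, 0.0) for g in np.unique(groups)},
                random_slope=False,
            )

    cov_re = np.atleast_2d(np.asarray(fit.cov_re))
    var_u0 = float(cov_re[0, 0])
    var_u1 = float(cov_re[1, 1]) if random_slope else 0.0
    corr = float(cov_re[0, 1] / np.sqrt(var_u0 * var_u1)) if random_slope and var_u0 > 0 and var_u1 > 0 else 0.0
    k = 2 + (4 if random_slope else 2)  # fixed effects + (variance components incl. resid)
    bic = -2.0 * float(fit.llf) + k * np.log(len(y))
    effects = {}
    for gname, vals in fit.random_effects.items():
        v = np.asarray(vals, dtype=float)
        effects[str(gname)] = (float(v[0]), float(v[1]) if v.size > 1 else 0.0)
    return LMEFit(
        beta0=float(fit.fe_params[0]),
        beta1=float(fit.fe_params[1]),
        se_beta0=float(fit.bse_fe[0]),
        se_beta1=float(fit.bse_fe[1]),
        var_u0=var_u0,
        var_u1=var_u1,
        var_e=float(fit.scale),
        corr_u=corr,
        loglik=float(fit.llf),
        bic=float(bic),
        plot_effects=effects,
        random_slope=random_slope,
    )


# --------------------------------------------------------------------------
# asymmetric-Laplace mixed quantile machinery (shared with the tree-level fit)
# --------------------------------------------------------------------------

def _ald_logpdf(e: np.ndarray, tau: float, sigma: float) -> np.ndarray:
    rho = e * (tau - (e < 0))
    return np.log(tau * (1.0 - tau) / sigma) - rho / sigma


def fit_ald_mixed(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    tau: float,
    *,
    fit_random: bool = True,
    n_nodes: int = 15,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> dict:
    """ML fit of y = X beta + u_g + e, e ~ ALD(0, sigma, tau), u ~ N(0, su^2).

    The Gaussian random intercept is integrated out with ``n_nodes``-point
    Gauss-Hermite quadrature. With ``fit_random=False`` the random-effect
    variance is pinned at zero and the fit is exactly tau-quantile regression.
    Returns a dict with beta, se, sigma, var_u0, loglik, plot_effects.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly inside (0, 1)")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    p = X.shape[1]
    order = np.argsort(groups, kind="stable")
    y_s, X_s = y[order], X[order]
    g_sorted = np.asarray(groups)[order]
    uniq, starts = np.unique(g_sorted, return_index=True)
    z, w = gauss_hermite(n_nodes)

    # start from least squares, shifted toward the requested quantile
    if start is None:
        beta0 = np.linalg.lstsq(X_s, y_s, rcond=None)[0]
        resid = y_s - X_s @ beta0
        if p > 0 and np.allclose(X_s[:, 0], 1.0):
            beta0[0] += float(np.quantile(resid, tau))
            resid = y_s - X_s @ beta0
        sigma0 = max(float(np.mean(np.abs(resid))), 1e-3)
        start = np.concatenate([beta0, [np.log(sigma0)], [np.log(0.3 * sigma0 + 1e-6)]])
    start = np.asarray(start, dtype=float)
    if not fit_random:
        start = start[: p + 1]

    def group_loglik(params: np.ndarray) -> np.ndarray:
        beta = params[:p]
        sigma = np.exp(params[p])
        r = y_s - X_s @ beta
        if not fit_random:
            return _ald_logpdf(r, tau, sigma)  # singleton groups: one obs each
        su = np.exp(params[p + 1])
        e = r[:, None] - (su * z)[None, :]  # (n, K)
        lp = _ald_logpdf(e, tau, sigma)
        grp = np.add.reduceat(lp, starts, axis=0)  # (G, K)
        return logsumexp_weighted(grp, w, axis=1)

    def negloglik(params: np.ndarray) -> float:
        return -float(np.sum(group_loglik(params)))

    res = maximize(negloglik, start, seed=seed)
    # polish through the kinks of the check function
    res2 = minimize(negloglik, res.x, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 6000, "maxfev": 6000})
    if np.isfinite(res2.fun) and res2.fun <= res.fun:
        res = res2
    params = res.x
    beta = params[:p]
    sigma = float(np.exp(params[p]))
    var_u0 = float(np.exp(params[p + 1]) ** 2) if fit_random else 0.0
    # BHHH scores rather than a numerical Hessian: the ALD kernel is kinked
    se = opg_se(group_loglik, params)
    if np.any(~np.isfinite(se[:p])):
        se = hessian_se(negloglik, params)

    effects: dict[str, float] = {}
    if fit_random:
        su = np.sqrt(var_u0)
        r = y_s - X_s @ beta
        e = r[:, None] - (su * z)[None, :]
        lp = np.add.reduceat(_ald_logpdf(e, tau, sigma), starts, axis=0)
        lw = w * np.exp(lp - lp.max(axis=1, keepdims=True))
        post = lw / lw.sum(axis=1, keepdims=True)
        u_hat = post @ (su * z)
        effects = {str(g): float(u) for g, u in zip(uniq, u_hat)}

    return {
        "beta": beta,
        "se_beta": se[:p],
        "sigma": sigma,
        "var_u0": var_u0,
        "loglik": -float(res.fun),
        "plot_effects": effects,
        "n_params": params.size,
        "n_obs": y.size,
    }


def fit_lqmm(
    plots: pd.DataFrame,
    tau: float = 0.95,
    *,
    fit_random: bool = True,
    n_nodes: int = 15,
    seed: int = 0,
    se_method: str = "hessian",
    n_boot: int = 200,
) -> QuantileFit:
    """Linear quantile mixed fit of ln N on ln dg at quantile ``tau``.

    ``se_method`` is "hessian" (numerical observed information, default) or
    "bootstrap" (resample plots with replacement, ``n_boot`` draws).
    """
    y, x, groups = _design(plots)
    X = np.column_stack([np.ones_like(x), x])
    out = fit_ald_mixed(y, X, groups, tau, fit_random=fit_random, n_nodes=n_nodes, seed=seed)
    se = out["se_beta"]
    if se_method == "bootstrap":
        se = _bootstrap_se(plots, tau, fit_random, n_nodes, seed, n_boot)
    k = out["n_params"]
    bic = -2.0 * out["loglik"] + k * np.log(out["n_obs"])
    return QuantileFit(
        tau=tau,
        beta0_tau=float(out["beta"][0]),
        beta1_tau=float(out["beta"][1]),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        var_u0=out["var_u0"],
        sigma_ala=out["sigma"],
        loglik=out["loglik"],
        plot_effects=out["plot_effects"],
        bic=bic,
    )


def _bootstrap_se(plots, tau, fit_random, n_nodes, seed, n_boot) -> np.ndarray:
    rng = np.random.default_rng(seed + 1)
    ids = plots["plot_id"].unique()
    ests = []
    for _ in range(n_boot):
        take = rng.choice(ids, size=ids.size, replace=True)
        frames = []
        for k, pid in enumerate(take):
            sub = plots[plots["plot_id"] == pid].copy()
            sub["plot_id"] = f"B{k}"
            frames.append(sub)
        bs = pd.concat(frames, ignore_index=True)
        try:
            y, x, groups = _design(bs)
            X = np.column_stack([np.ones_like(x), x])
            out = fit_ald_mixed(y, X, groups, tau, fit_random=fit_random,
                                n_nodes=n_nodes, seed=seed)
            ests.append(out["beta"])
        except ConvergenceError:
            continue
    if len(ests) < 10:
        raise ConvergenceError("bootstrap failed on almost every resample")
    return np.std(np.asarray(ests), axis=0, ddof=1)


def select_quantile(plots: pd.DataFrame, taus, **kwargs) -> tuple[float, pd.DataFrame]:
    """Pick the quantile giving the lowest summed sampling variance of (b0, b1).

    Fits the LQMM at every candidate tau; candidates that fail to converge are
    excluded with a warning. Returns (best tau, full comparison table).
    """
    taus = list(taus)
    if not taus:
        raise ValueError("empty candidate set")
    rows = []
    for tau in taus:
        try:
            fit = fit_lqmm(plots, tau=tau, **kwargs)
        except (ConvergenceError, ValueError) as err:
            warnings.warn(f"tau={tau} excluded: {err}")
            continue
        rows.append(dict(tau=tau, beta0=fit.beta0_tau, beta1=fit.beta1_tau,
                         se_beta0=fit.se_beta0, se_beta1=fit.se_beta1,
                         var_sum=fit.se_beta0**2 + fit.se_beta1**2,
                         loglik=fit.loglik))
    if not rows:
        raise ConvergenceError("every candidate quantile failed")
    table = pd.DataFrame(rows)
    best = float(table.loc[table["var_sum"].idxmin(), "tau"])
    return best, table


# --------------------------------------------------------------------------
# S-P-SFMM
# --------------------------------------------------------------------------

def composed_error_logpdf(e: np.ndarray, sigma_v: float, sigma_u: float) -> np.ndarray:
    """log density of V - U, V ~ N(0, sv^2), U ~ half-normal(su^2):
    (2/sigma) phi(e/sigma) Phi(-e lambda / sigma)."""
    sigma = np.hypot(sigma_v, sigma_u)
    lam = sigma_u / sigma_v
    return np.log(2.0) + norm.logpdf(e / sigma) - np.log(sigma) + norm.logcdf(-e * lam / sigma)


def fit_sfmm(
    plots: pd.DataFrame,
    *,
    include_random: bool = True,
    n_nodes: int = 15,
    method: str = "quadrature",
    n_sim: int = 400,
    seed: int = 0,
) -> FrontierFit:
    """Stochastic frontier fit with plot random intercept (true random-effects SFR).

    ln N = b0 + w_i + b1 ln dg + V - U. The plot intercept w_i is integrated
    by Gauss-Hermite quadrature (``method="quadrature"``) or by simulated ML
    over ``n_sim`` fixed standard-normal draws (``method="sml"``). Warns when
    the inefficiency scale is pinned at zero (frontier collapses to OLS).
    """
    y, x, groups = _design(plots)
    X = np.column_stack([np.ones_like(x), x])
    order = np.argsort(groups, kind="stable")
    y_s, X_s = y[order], X[order]
    g_sorted = np.asarray(groups)[order]
    uniq, starts_idx = np.unique(g_sorted, return_index=True)
    if method == "quadrature":
        z, w = gauss_hermite(n_nodes)
    elif method == "sml":
        z = np.random.default_rng(12345).standard_normal(n_sim)  # fixed draws: smooth SML objective
        w = np.full(n_sim, 1.0 / n_sim)
    else:
        raise ValueError(f"unknown method {method!r}")

    beta_ols, *_ = np.linalg.lstsq(X_s, y_s, rcond=None)
    resid = y_s - X_s @ beta_ols
    s = float(np.std(resid))
    start = np.concatenate([beta_ols, [np.log(0.8 * s + 1e-6), np.log(0.8 * s + 1e-6),
                                       np.log(0.3 * s + 1e-6)]])
    if not include_random:
        start = start[:-1]

    def negloglik(params: np.ndarray) -> float:
        beta = params[:2]
        sv, su = np.exp(params[2]), np.exp(params[3])
        r = y_s - X_s @ beta
        if not include_random:
            return -float(np.sum(composed_error_logpdf(r, sv, su)))
        sw = np.exp(params[4])
        e = r[:, None] - (sw * z)[None, :]
        lp = composed_error_logpdf(e, sv, su)
        grp = np.add.reduceat(lp, starts_idx, axis=0)
        return -float(np.sum(logsumexp_weighted(grp, w, axis=1)))

    res = maximize(negloglik, start, seed=seed)
    params = res.x
    beta = params[:2]
    sigma_v, sigma_u = float(np.exp(params[2])), float(np.exp(params[3]))
    var_w = float(np.exp(params[4]) ** 2) if include_random else 0.0
    if sigma_u < 1e-2 * sigma_v:
        warnings.warn("no inefficiency signal; frontier ~= OLS")
    se = hessian_se(negloglik, params)

    effects: dict[str, float] = {}
    if include_random:
        sw = np.sqrt(var_w)
        r = y_s - X_s @ beta
        e = r[:, None] - (sw * z)[None, :]
        lp = np.add.reduceat(composed_error_logpdf(e, sigma_v, sigma_u), starts_idx, axis=0)
        lw = w * np.exp(lp - lp.max(axis=1, keepdims=True))
        post = lw / lw.sum(axis=1, keepdims=True)
        effects = {str(g): float(u) for g, u in zip(uniq, post @ (sw * z))}

    k = params.size
    bic = 2.0 * res.fun + k * np.log(y.size)
    return FrontierFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        sigma_v=sigma_v,
        sigma_u=sigma_u,
        var_u0re=var_w,
        loglik=-float(res.fun),
        bic=float(bic),
        plot_effects=effects,
    )
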