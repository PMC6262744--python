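"""Dynamic (remeasured-plot) strategies for the size-density relationship.

Three models use the information in repeated measurements:

* **density model (D-P-LME)** — the closed-form solution of the mortality ODE
  dN/ddg = -e^b0 dg^b1 N^b2 links consecutive measurements:

      ln N1 = (1/(1-b2)) ln[ N0^(1-b2) + e^b0 ((1-b2)/(b1+1)) (dg0^(b1+1) - dg1^(b1+1)) ] + e

  fitted as a nonlinear mixed model with Gaussian residuals and a Gaussian
  plot random effect on one or all of (b0, b1, b2); candidate random-effect
  placements are compared by BIC.

* **mortality model (D-P-NBME)** — deaths between occasions as negative
  binomial counts with log link

      ln mu = b0 + u0i + b1 ln dg0 + b2 ln N0 + ln(delta dg)   (offset, no coefficient)
      Var   = mu + mu^2 / theta

  with a Gaussian plot random intercept integrated by Gauss-Hermite
  quadrature. Counts are deaths per plot: density differences are converted
  with the plot area (NB requires integers; the rounding is logged).

* **trajectory model (D-P-NLME)** — predicts stand diameter from density,
  anchoring each plot's trajectory at its first measurement:

      ln dg = a0 + a1 ln N - [(a0 a2)^2 / (a0 + a1 ln N1st - ln dg1st)] exp(-a3 (ln N1st - ln N))

  The reversed-Reineke part (a0, a1) carries the self-thinning line; the
  exponential term decays the initial displacement from that line as density
  falls below its first-measurement value.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._optim import gauss_hermite, hessian_se, logsumexp_weighted, maximize

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionRecord",
    "DensityFit",
    "MortalityFit",
    "TrajectoryFit",
    "build_transitions",
    "density_closed_form",
    "fit_density_model",
    "fit_mortality_nbme",
    "fit_trajectory_nlme",
    "trajectory_mean",
]


@dataclass(frozen=True)
class TransitionRecord:
    plot_id: str
    N0: float
    N1: float
    dg0: float
    dg1: float

    @property
    def delta_n(self) -> float:
        return self.N0 - self.N1

    @property
    def delta_dg(self) -> float:
        return self.dg1 - self.dg0


@dataclass
class DensityFit:
    beta0: float
    beta1: float
    beta2: float
    ses: tuple[float, float, float]
    random_effect_spec: tuple[str, ...]
    re_sds: dict[str, float]
    sigma_e: float
    loglik: float
    bic: float
    comparison: pd.DataFrame = field(default_factory=pd.DataFrame)
    plot_effects: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class MortalityFit:
    beta0: float
    beta1: float
    beta2: float
    theta: float
    var_u0: float
    ses: tuple[float, float, float]
    loglik: float
    bic: float
    plot_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class TrajectoryFit:
    alpha0: float
    alpha1: float
    alpha2: float
    alpha3: float
    ses: tuple[float, float, float, float]
    var_u0: float
    sigma_e: float
    loglik: float
    bic: float


# --------------------------------------------------------------------------
# transitions
# --------------------------------------------------------------------------

def build_transitions(plots: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-occasion transition records from a long plot table.

    Keeps plots with >= 2 occasions; transitions with ingrowth (N1 > N0) or
    non-increasing dg are excluded and logged. Returns columns plot_id, N0,
    N1, dg0, dg1, delta_n, delta_dg (empty frame allowed, with a warning).
    """
    rows = []
    n_dropped = 0
    for pid, grp in plots.sort_values(["plot_id", "occasion"]).groupby("plot_id"):
        if len(grp) < 2:
            continue
        vals = grp[["n_ha", "dg_cm"]].to_numpy(dtype=float)
        for j in range(len(vals) - 1):
            n0, dg0 = vals[j]
            n1, dg1 = vals[j + 1]
            if n1 > n0:
                n_dropped += 1
                logger.info("dropped transition %s occ %d->%d: ingrowth (N1 > N0)", pid, j, j + 1)
                continue
            if dg1 <= dg0:
                n_dropped += 1
                logger.info("dropped transition %s occ %d->%d: dg non-increasing", pid, j, j + 1)
                continue
            rows.append(dict(plot_id=pid, N0=n0, N1=n1, dg0=dg0, dg1=dg1,
                             delta_n=n0 - n1, delta_dg=dg1 - dg0))
    if n_dropped:
        logger.warning("build_transitions: excluded %d transitions", n_dropped)
    out = pd.DataFrame(rows, columns=["plot_id", "N0", "N1", "dg0", "dg1", "delta_n", "delta_dg"])
    if out.empty:
        warnings.warn("no usable transitions")
    return out


# --------------------------------------------------------------------------
# density model
# --------------------------------------------------------------------------

_PENALTY = 1e4
_PEN_SCALE = 1e8  # per-unit hinge on smooth feasibility violations


def density_closed_form(b0, b1, b2, N0, dg0, dg1):
    """Predicted ln N1 from the ODE solution; -inf where the bracket dies."""
    p = b1 + 1.0
    q = 1.0 - b2
    with np.errstate(over="ignore", invalid="ignore"):
        bracket = N0**q + np.exp(b0) * (q / p) * (dg0**p - dg1**p)
        out = np.where(bracket > 0, np.log(np.maximum(bracket, 1e-300)) / q, -np.inf)
    return out


def _density_mu_pen(b0, b1, b2, N0, dg0, dg1):
    """Smooth surrogate of the closed form for optimization: the bracket is
    floored at a tiny positive value and the violation returned as a hinge
    penalty, so the objective keeps a usable gradient in infeasible regions."""
    p = b1 + 1.0
    q = 1.0 - b2
    with np.errstate(over="ignore", invalid="ignore"):
        bracket = N0**q + np.exp(b0) * (q / p) * (dg0**p - dg1**p)
    floor = 1e-12
    mu = np.log(np.maximum(bracket, floor)) / q
    pen = np.maximum(0.0, floor - bracket)
    return mu, pen


def fit_density_model(
    transitions: pd.DataFrame,
    random_effect_specs=(("beta0",), ("beta1",), ("beta2",), ("beta0", "beta1", "beta2")),
    *,
    n_nodes: int = 9,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> DensityFit:
    """Nonlinear mixed fit of the closed-form density model.

    Every candidate random-effect placement in ``random_effect_specs`` is
    fitted (independent Gaussian effects, tensor-product Gauss-Hermite
    quadrature) and the best-BIC variant is returned together with the full
    comparison table. Parameter proposals that extinguish the trajectory are
    penalized rather than allowed to crash the optimizer.
    """
    if len(transitions) < 2:
        raise ValueError("need transitions to fit")
    N0 = transitions["N0"].to_numpy(dtype=float)
    dg0 = transitions["dg0"].to_numpy(dtype=float)
    dg1 = transitions["dg1"].to_numpy(dtype=float)
    y = np.log(transitions["N1"].to_numpy(dtype=float))
    groups = transitions["plot_id"].to_numpy()
    order = np.argsort(groups, kind="stable")
    N0s, dg0s, dg1s, ys = N0[order], dg0[order], dg1[order], y[order]
    uniq, starts_idx = np.unique(groups[order], return_index=True)

    if start is None:
        # crude start: Reineke-like slope -1.6 attractor with b2 = 2
        start = np.array([np.log(1.6) - 12.0, 0.6, 2.0])

    results = []
    for spec in random_effect_specs:
        spec = tuple(spec)
        res = _fit_density_spec(ys, N0s, dg0s, dg1s, starts_idx, uniq, spec,
                                start, n_nodes, seed)
        results.append(res)
    table = pd.DataFrame(
        [dict(spec="+".join(r["spec"]) if r["spec"] else "none", loglik=r["loglik"],
              bic=r["bic"], converged=r["ok"]) for r in results]
    )
    ok = [r for r in results if r["ok"]]
    if not ok:
        raise RuntimeError("density model failed to converge for every random-effect spec")
    best = min(ok, key=lambda r: r["bic"])
    effects = _density_plot_effects(best, ys, N0s, dg0s, dg1s, starts_idx, uniq, n_nodes)
    return DensityFit(
        beta0=best["beta"][0], beta1=best["beta"][1], beta2=best["beta"][2],
        ses=tuple(best["se"][:3]),
        random_effect_spec=best["spec"],
        re_sds=best["re_sds"],
        sigma_e=best["sigma_e"],
        loglik=best["loglik"],
        bic=best["bic"],
        comparison=table,
        plot_effects=effects,
    )


def _density_plot_effects(best, y, N0, dg0, dg1, starts_idx, uniq, n_nodes):
    """Posterior-mean random effects per plot for the winning spec."""
    spec = best["spec"]
    if not spec:
        return {}
    idx = {"beta0": 0, "beta1": 1, "beta2": 2}
    re_pos = [idx[s] for s in spec]
    sds = np.array([best["re_sds"][s] for s in spec])
    n_re = len(re_pos)
    nodes_1d, w_1d = gauss_hermite(n_nodes if n_re == 1 else 5)
    combos = list(itertools.product(*([range(len(nodes_1d))] * n_re)))
    Z = np.array([[nodes_1d[k] for k in c] for c in combos])
    W = np.array([np.prod([w_1d[k] for k in c]) for c in combos])
    sigma_e = best["sigma_e"]
    beta = best["beta"]
    lp = np.empty((y.size, Z.shape[0]))
    for k in range(Z.shape[0]):
        b = np.array(beta, dtype=float)
        b[re_pos] = b[re_pos] + sds * Z[k]
        mu = density_closed_form(b[0], b[1], b[2], N0, dg0, dg1)
        bad = ~np.isfinite(mu)
        lp[:, k] = (-0.5 * ((y - np.where(bad, y, mu)) / sigma_e) ** 2 - _PENALTY * bad)
    grp = np.add.reduceat(lp, starts_idx, axis=0)
    lw = W * np.exp(grp - grp.max(axis=1, keepdims=True))
    post = lw / lw.sum(axis=1, keepdims=True)
    u_hat = post @ (Z * sds)  # (G, n_re)
    return {str(g): dict(zip(spec, map(float, u))) for g, u in zip(uniq, u_hat)}


def _fit_density_spec(y, N0, dg0, dg1, starts_idx, uniq, spec, start, n_nodes, seed):
    idx = {"beta0": 0, "beta1": 1, "beta2": 2}
    re_pos = [idx[s] for s in spec]
    n_re = len(re_pos)
    # tensor-product quadrature over the random effects in the spec
    if n_re:
        nodes_1d, w_1d = gauss_hermite(n_nodes if n_re == 1 else 5)
        grids = list(itertools.product(*([range(len(nodes_1d))] * n_re)))
        Z = np.array([[nodes_1d[k] for k in combo] for combo in grids])  # (K, n_re)
        W = np.array([np.prod([w_1d[k] for k in combo]) for combo in grids])
    sd0 = 0.1

    x0 = np.concatenate([start, [np.log(0.05)], np.full(n_re, np.log(sd0))])

    def negloglik(params):
        beta = params[:3]
        sigma_e = np.exp(params[3])
        if not n_re:
            mu, pen = _density_mu_pen(*beta, N0, dg0, dg1)
            nll = 0.5 * np.sum((y - mu) ** 2) / sigma_e**2 + y.size * np.log(sigma_e) \
                + 0.5 * y.size * np.log(2 * np.pi) + _PEN_SCALE * np.sum(pen)
            return float(nll)
        sds = np.exp(params[4:4 + n_re])
        K = Z.shape[0]
        lp = np.empty((y.size, K))
        for k in range(K):
            b = np.array(beta, dtype=float)
            b[re_pos] = b[re_pos] + sds * Z[k]
            mu, pen = _density_mu_pen(b[0], b[1], b[2], N0, dg0, dg1)
            lp[:, k] = (-0.5 * ((y - mu) / sigma_e) ** 2 - np.log(sigma_e)
                        - 0.5 * np.log(2 * np.pi) - _PEN_SCALE * pen)
        grp = np.add.reduceat(lp, starts_idx, axis=0)
        return -float(np.sum(logsumexp_weighted(grp, W, axis=1)))

    try:
        res = maximize(negloglik, x0, seed=seed, restarts=3)
        if not n_re:
            # Gauss-Newton polish of the fixed-effect fit (exact on clean data)
            from scipy.optimize import least_squares

            def resid(beta):
                mu, pen = _density_mu_pen(*beta, N0, dg0, dg1)
                return np.concatenate([y - mu, 1e4 * pen])

            ls = least_squares(resid, res.x[:3], xtol=1e-15, ftol=1e-15, gtol=1e-15)
            sig = max(float(np.sqrt(np.mean(ls.fun[: y.size] ** 2))), 1e-12)
            cand = np.concatenate([ls.x, [np.log(sig)]])
            if negloglik(cand) <= res.fun:
                res.x, res.fun = cand, negloglik(cand)
        se = hessian_se(negloglik, res.x)
        k_par = res.x.size
        bic = 2.0 * res.fun + k_par * np.log(y.size)
        return dict(spec=spec, beta=res.x[:3], sigma_e=float(np.exp(res.x[3])),
                    re_sds={s: float(np.exp(v)) for s, v in zip(spec, res.x[4:4 + n_re])},
                    se=se, loglik=-float(res.fun), bic=float(bic), ok=True)
    except Exception as err:  # noqa: BLE001 - candidate specs may legitimately fail
        logger.warning("density spec %s failed: %s", spec, err)
        return dict(spec=spec, beta=None, sigma_e=np.nan, re_sds={}, se=None,
                    loglik=-np.inf, bic=np.inf, ok=False)


# --------------------------------------------------------------------------
# mortality model
# --------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 log-pmf with mean mu and Var = mu + mu^2/theta."""
    mu = np.clip(mu, 1e-12, 1e300)  # line searches can propose wild means
    return (gammaln(k + theta) - gammaln(theta) - gammaln(k + 1)
            + theta * (np.log(theta) - np.log(theta + mu))
            + k * (np.log(mu) - np.log(theta + mu)))


def nb_mean(coeffs, dg0, n0, ddg):
    """Per-hectare mortality mean of the log-link model:
    mu = exp(b0 + b1 ln dg0 + b2 ln N0 + ln ddg)."""
    b0, b1, b2 = coeffs
    return np.exp(b0 + b1 * np.log(dg0) + b2 * np.log(n0) + np.log(ddg))


def deaths_from_transitions(transitions: pd.DataFrame, area_m2) -> pd.DataFrame:
    """Convert per-hectare density losses into per-plot death counts.

    ``area_m2`` is a scalar or a per-row series; deaths = round(delta_n *
    area/10000). The rounding applied to each plot is logged.
    """
    area = np.broadcast_to(np.asarray(area_m2, dtype=float), (len(transitions),))
    out = transitions.copy()
    raw = out["delta_n"].to_numpy(dtype=float) * area / 10000.0
    out["area_m2"] = area
    out["deaths_count"] = np.round(raw).astype(int)
    for pid, r, c in zip(out["plot_id"], raw, out["deaths_count"]):
        logger.info("plot %s: %0.2f deaths/plot rounded to %d", pid, r, c)
    out = out.rename(columns={"N0": "n0_ha", "dg0": "dg0_cm", "dg1": "dg1_cm"})
    return out


def fit_mortality_nbme(
    deaths: pd.DataFrame,
    *,
    fit_random: bool = True,
    n_nodes: int = 15,
    seed: int = 0,
    theta_fixed: float | None = None,
) -> MortalityFit:
    """NB mixed mortality fit on a death-count table.

    ``deaths`` needs columns plot_id, deaths_count, n0_ha, dg0_cm, dg1_cm,
    area_m2 (see :func:`deaths_from_transitions`). The linear predictor is
    ln mu_count = b0 + u0i + b1 ln dg0 + b2 ln N0 + ln(delta dg) + ln(area/1e4),
    the last two terms fixed offsets (the model is per-hectare; the area term
    converts its mean to the plot's count scale).
    """
    k = deaths["deaths_count"].to_numpy(dtype=float)
    if np.all(k == 0):
        raise ValueError("no mortality signal: every death count is zero")
    dg0 = deaths["dg0_cm"].to_numpy(dtype=float)
    n0 = deaths["n0_ha"].to_numpy(dtype=float)
    ddg = deaths["dg1_cm"].to_numpy(dtype=float) - dg0
    area = deaths["area_m2"].to_numpy(dtype=float)
    offset = np.log(ddg) + np.log(area / 10000.0)
    X = np.column_stack([np.ones_like(dg0), np.log(dg0), np.log(n0)])
    groups = deaths["plot_id"].to_numpy()
    order = np.argsort(groups, kind="stable")
    k_s, X_s, off_s = k[order], X[order], offset[order]
    uniq, starts_idx = np.unique(groups[order], return_index=True)
    z, w = gauss_hermite(n_nodes)

    # Poisson-regression moment start
    beta_start = np.linalg.lstsq(X_s, np.log(np.maximum(k_s, 0.5)) - off_s, rcond=None)[0]
    free_theta = theta_fixed is None
    x0 = np.concatenate([beta_start,
                         [np.log(5.0)] if free_theta else [],
                         [np.log(0.1)] if fit_random else []])
    i_th = 3  # index of log-theta when free; log-su follows the theta slot

    def negloglik(params):
        beta = params[:3]
        theta = np.exp(params[i_th]) if free_theta else theta_fixed
        eta = np.clip(X_s @ beta + off_s, -700.0, 700.0)
        if not fit_random:
            return -float(np.sum(_nb_logpmf(k_s, np.exp(eta), theta)))
        su = np.exp(params[-1])
        lp = _nb_logpmf(k_s[:, None],
                        np.exp(np.clip(eta[:, None] + su * z[None, :], -700.0, 700.0)), theta)
        grp = np.add.reduceat(lp, starts_idx, axis=0)
        return -float(np.sum(logsumexp_weighted(grp, w, axis=1)))

    res = maximize(negloglik, x0, seed=seed)
    from scipy.optimize import minimize as _minimize

    polish = _minimize(negloglik, res.x, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000, "maxfev": 4000})
    if np.isfinite(polish.fun) and polish.fun <= res.fun:
        res = polish
    params = res.x
    theta = float(np.exp(params[i_th])) if free_theta else float(theta_fixed)
    if theta > 1e4:
        warnings.warn("theta very large: dispersion is Poisson-like")
    var_u0 = float(np.exp(params[-1]) ** 2) if fit_random else 0.0
    se = hessian_se(negloglik, params)
    bic = 2.0 * res.fun + params.size * np.log(k.size)

    effects: dict[str, float] = {}
    if fit_random:
        su = np.sqrt(var_u0)
        eta = X_s @ params[:3] + off_s
        lp = np.add.reduceat(_nb_logpmf(k_s[:, None], np.exp(eta[:, None] + su * z[None, :]), theta),
                             starts_idx, axis=0)
        lw = w * np.exp(lp - lp.max(axis=1, keepdims=True))
        post = lw / lw.sum(axis=1, keepdims=True)
        effects = {str(g): float(u) for g, u in zip(uniq, post @ (su * z))}

    return MortalityFit(
        beta0=float(params[0]), beta1=float(params[1]), beta2=float(params[2]),
        theta=theta, var_u0=var_u0, ses=tuple(se[:3]),
        loglik=-float(res.fun), bic=float(bic), plot_effects=effects,
    )


# --------------------------------------------------------------------------
# trajectory model
# --------------------------------------------------------------------------

def trajectory_mean(alpha, lnN, lnN1st, lndg1st):
    """Adopted reading of the first-measurement trajectory mean function.

    ln dg = a0 + a1 lnN - [(a0 a2)^2 / (a0 + a1 lnN1st - lndg1st)] e^{-a3 (lnN1st - lnN)}.
    The grouping of the displacement term is isolated here so an alternative
    reading of the printed equation is a one-line change. Returns -inf where
    the anchor denominator is non-positive.
    """
    a0, a1, a2, a3 = alpha
    denom = a0 + a1 * lnN1st - lndg1st
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(
            denom > 0,
            a0 + a1 * lnN - ((a0 * a2) ** 2 / np.where(denom > 0, denom, 1.0))
            * np.exp(-a3 * (lnN1st - lnN)),
            -np.inf,
        )
    return out


def _traj_mu_pen(alpha, lnN, lnN1st, lndg1st):
    """Smooth fitting surrogate of trajectory_mean: anchor denominator floored
    at a small positive value, violation returned as a hinge penalty."""
    a0, a1, a2, a3 = alpha
    denom = a0 + a1 * lnN1st - lndg1st
    floor = 1e-6
    d_safe = np.maximum(denom, floor)
    expo = np.clip(-a3 * (lnN1st - lnN), -60.0, 60.0)
    mu = a0 + a1 * lnN - ((a0 * a2) ** 2 / d_safe) * np.exp(expo)
    pen = np.maximum(0.0, floor - denom)
    return mu, pen


def fit_trajectory_nlme(
    plots: pd.DataFrame,
    *,
    fit_random: bool = False,
    n_nodes: int = 9,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> TrajectoryFit:
    """Fit the first-measurement trajectory model on remeasured plots.

    Each plot's first occasion supplies the anchor (N1st, dg1st), which the
    model conditions on; the later occasions contribute the ln dg responses
    (the anchor row is not also a response — it would enter with zero
    residual by construction and bias the error variance). Gaussian ML,
    optionally with a plot random intercept on a0 (Gauss-Hermite).
    """
    dyn = plots[plots.groupby("plot_id")["occasion"].transform("count") >= 2]
    if dyn["plot_id"].nunique() < 2:
        raise ValueError("need >= 2 plots with >= 2 occasions")
    dyn = dyn.sort_values(["plot_id", "occasion"])
    firsts = dyn.groupby("plot_id").first()
    later = dyn[dyn.groupby("plot_id").cumcount() > 0]
    lnN = np.log(later["n_ha"].to_numpy(dtype=float))
    lndg = np.log(later["dg_cm"].to_numpy(dtype=float))
    lnN1 = np.log(firsts.loc[later["plot_id"], "n_ha"].to_numpy(dtype=float))
    lndg1 = np.log(firsts.loc[later["plot_id"], "dg_cm"].to_numpy(dtype=float))
    groups = later["plot_id"].to_numpy()
    order = np.argsort(groups, kind="stable")
    lnN, lndg, lnN1, lndg1 = lnN[order], lndg[order], lnN1[order], lndg1[order]
    uniq, starts_idx = np.unique(groups[order], return_index=True)

    if start is None:
        # reversed-Reineke start from an OLS of lndg on lnN; the displacement
        # amplitude (a0 a2)^2 should match the typical first-measurement gap
        b = np.polyfit(lnN, lndg, 1)
        a0_s, a1_s = float(b[1]), float(b[0])
        gaps = a0_s + a1_s * lnN1[starts_idx] - lndg1[starts_idx]
        gap_typ = float(np.median(np.abs(gaps))) or 0.1
        start = np.array([a0_s, a1_s, gap_typ / max(abs(a0_s), 1e-6), 1.0])
    z, w = gauss_hermite(n_nodes)

    x0 = np.concatenate([start, [np.log(0.05)], [np.log(0.05)] if fit_random else []])

    def negloglik(params):
        alpha = params[:4]
        sigma = np.exp(params[4])
        if not fit_random:
            mu, pen = _traj_mu_pen(alpha, lnN, lnN1, lndg1)
            return float(0.5 * np.sum((lndg - mu) ** 2) / sigma**2
                         + lndg.size * np.log(sigma)
                         + 0.5 * lndg.size * np.log(2 * np.pi) + _PEN_SCALE * pen.sum())
        su = np.exp(params[5])
        lp = np.empty((lndg.size, z.size))
        for kk, zz in enumerate(z):
            a0k = alpha[0] + su * zz
            mu, pen = _traj_mu_pen((a0k, alpha[1], alpha[2], alpha[3]), lnN, lnN1, lndg1)
            lp[:, kk] = (-0.5 * ((lndg - mu) / sigma) ** 2
                         - np.log(sigma) - 0.5 * np.log(2 * np.pi) - _PEN_SCALE * pen)
        grp = np.add.reduceat(lp, starts_idx, axis=0)
        return -float(np.sum(logsumexp_weighted(grp, w, axis=1)))

    res = maximize(negloglik, x0, seed=seed)
    if not fit_random:
        # Gauss-Newton polish (guards against ridge excursions of quasi-Newton)
        from scipy.optimize import least_squares

        def resid(alpha):
            mu, pen = _traj_mu_pen(alpha, lnN, lnN1, lndg1)
            return np.concatenate([lndg - mu, 1e4 * pen])

        guesses = [res.x[:4]] + [
            np.array([x0[0], x0[1], x0[2], a3]) for a3 in (0.25, 0.5, 1.0, 2.0, 4.0)
        ]
        for guess in guesses:
            ls = least_squares(resid, guess, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            sig = max(float(np.sqrt(np.mean(ls.fun[: lndg.size] ** 2))), 1e-12)
            cand = np.concatenate([ls.x, [np.log(sig)]])
            if negloglik(cand) < res.fun:
                res.x, res.fun = cand, negloglik(cand)
    se = hessian_se(negloglik, res.x)
    bic = 2.0 * res.fun + res.x.size * np.log(lndg.size)
    return TrajectoryFit(
        alpha0=float(res.x[0]), alpha1=float(res.x[1]),
        alpha2=float(res.x[2]), alpha3=float(res.x[3]),
        ses=tuple(se[:4]),
        var_u0=float(np.exp(res.x[5]) ** 2) if fit_random else 0.0,
        sigma_e=float(np.exp(res.x[4])),
        loglik=-float(res.fun), bic=float(bic),
    )
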