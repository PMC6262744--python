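"""Shared maximum-likelihood machinery: restart optimizer, quadrature, Hessian SEs."""

from __future__ import annotations

import warnings

import numpy as np
from numpy.polynomial.hermite_e import hermegauss  # probabilists' Hermite
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess


class ConvergenceError(RuntimeError):
    """Raised when an ML fit fails to converge; carries the best iterate."""

    def __init__(self, message: str, best_params=None, best_value=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_value = best_value


def gauss_hermite(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(Z)], Z ~ N(0,1): sum_k w_k f(z_k), sum w_k = 1."""
    z, w = hermegauss(n_nodes)
    return z, w / w.sum()


def maximize(
    negloglik,
    x0: np.ndarray,
    *,
    restarts: int = 5,
    jitter: float = 0.3,
    seed: int = 0,
    tol: float = 1e-8,
    method: str = "BFGS",
):
    """Quasi-Newton maximization with jittered restarts.

    Minimizes ``negloglik`` from ``x0`` and from ``restarts`` jittered starts,
    keeping the best finite optimum. Returns the scipy OptimizeResult of the
    winner. Raises ConvergenceError if no start produces a finite optimum.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    best = None
    scale = np.maximum(np.abs(x0), 0.1)  # jitter proportional to parameter magnitude
    starts = [x0] + [x0 + jitter * scale * rng.standard_normal(x0.size) for _ in range(restarts)]
    for start in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = minimize(negloglik, start, method=method, options={"gtol": tol, "maxiter": 2000})
            except Exception:
                continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        # a clean converged solution from the unjittered start is good enough
        if best is not None and start is x0 and res.success:
            break
    if best is None:
        raise ConvergenceError("optimizer failed from every start", best_params=x0)
    return best


def hessian_se(negloglik, params: np.ndarray) -> np.ndarray:
    """Standard errors from the inverse numerical Hessian of -loglik.

    Entries whose curvature is not positive definite come back NaN rather
    than raising, so callers can fall back to bootstrap.
    """
    params = np.asarray(params, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(params, negloglik)
        cov = np.linalg.pinv(hess)  # pinv: variance parameters may sit on a boundary
        var = np.diag(cov)
        se = np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
    except np.linalg.LinAlgError:
        se = np.full(params.size, np.nan)
    return se


def opg_se(group_loglik, params: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """BHHH standard errors from per-group score outer products.

    ``group_loglik(params)`` returns the vector of independent per-group
    log-likelihood contributions. Central-difference scores are far more
    stable than a full numerical Hessian on kinked likelihoods (ALD kernels).
    """
    params = np.asarray(params, dtype=float)
    k = params.size
    scores = None
    for j in range(k):
        step = np.zeros(k)
        step[j] = eps * max(1.0, abs(params[j]))
        gp = group_loglik(params + step)
        gm = group_loglik(params - step)
        col = (np.asarray(gp) - np.asarray(gm)) / (2.0 * step[j])
        if scores is None:
            scores = np.empty((col.size, k))
        scores[:, j] = col
    info = scores.T @ scores
    try:
        cov = np.linalg.pinv(info)  # boundary variance components give null scores
        var = np.diag(cov)
        return np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def logsumexp_weighted(logvals: np.ndarray, weights: np.ndarray, axis: int = -1) -> np.ndarray:
    """log sum_k w_k exp(logvals_k), numerically stable."""
    m = np.max(logvals, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(weights * np.exp(logvals - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out
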