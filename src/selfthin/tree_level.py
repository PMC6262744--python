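"""Tree-level (additive stand-density) frontier strategy.

Instead of plot aggregates, this strategy builds per-plot density covariates
from the tree list itself, in metric stand-density-index units relative to a
reference tree of 25.4 cm diameter (the classical 10-inch reference):

    x0 = sum_z EF_z (d_z / 25.4)^1.6 / 100
    x1 = sum_z EF_z SG_z (d_z / 25.4)^1.6 / 100

so a uniform stand at d = 25.4 cm has x0 = N/100 and the unit constraint

    a0 x0 + a1 x1 + e = 1

fitted at the 95th percentile (ALD mixed quantile fit with a plot random
intercept, no model intercept) gives each plot's maximum density through

    Nmax = 100 / (a0 + a1 * SGbar)

where SGbar is the plot's average wood specific gravity (basal-area-weighted
by default). Wood density enters because denser-wooded species pack fewer
stems at a given size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .static_frontier import fit_ald_mixed
from ._optim import hessian_se

REFERENCE_DIAMETER = 25.4  # cm
REINEKE_EXPONENT = 1.6
SDI_SCALE = 100.0

__all__ = [
    "DuceyCovariates",
    "TreeLevelFit",
    "compute_ducey_covariates",
    "covariate_table",
    "fit_tree_level_frontier",
    "nmax_from_tree_fit",
]


@dataclass
class DuceyCovariates:
    plot_id: str
    occasion: int
    x0: float  # hundreds of metric SDI units
    x1: float  # specific-gravity-weighted analogue
    sg_bar: float  # plot mean specific gravity


@dataclass
class TreeLevelFit:
    alpha0: float
    alpha1: float
    se_alpha0: float
    se_alpha1: float
    var_u0: float
    loglik: float
    tau: float = 0.95
    plot_effects: dict[str, float] = field(default_factory=dict)


def compute_ducey_covariates(
    trees: pd.DataFrame,
    *,
    dref: float = REFERENCE_DIAMETER,
    scale: float = SDI_SCALE,
    sg_weighting: str = "basal_area",
) -> DuceyCovariates:
    """Additive density covariates for one plot-occasion tree list.

    ``trees`` needs columns d_cm, sg, ef (plus plot_id/occasion). ``sg_bar``
    is the basal-area-weighted mean specific gravity by default
    (``sg_weighting="arithmetic"`` for the plain mean over EF).
    """
    if len(trees) == 0:
        raise ValueError("no trees")
    if trees["sg"].isna().any():
        raise ValueError("missing specific gravity; supply a species-default table upstream")
    d = trees["d_cm"].to_numpy(dtype=float)
    ef = trees["ef"].to_numpy(dtype=float)
    sg = trees["sg"].to_numpy(dtype=float)
    size_term = ef * (d / dref) ** REINEKE_EXPONENT
    x0 = float(size_term.sum() / scale)
    x1 = float((sg * size_term).sum() / scale)
    if sg_weighting == "basal_area":
        w = ef * d**2
    elif sg_weighting == "arithmetic":
        w = ef
    else:
        raise ValueError(f"unknown sg_weighting {sg_weighting!r}")
    sg_bar = float((w * sg).sum() / w.sum())
    pid = str(trees["plot_id"].iloc[0]) if "plot_id" in trees else ""
    occ = int(trees["occasion"].iloc[0]) if "occasion" in trees else 0
    return DuceyCovariates(plot_id=pid, occasion=occ, x0=x0, x1=x1, sg_bar=sg_bar)


def covariate_table(trees: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """compute_ducey_covariates applied per plot-occasion; auditable CSV shape."""
    rows = []
    for (pid, occ), grp in trees.groupby(["plot_id", "occasion"], sort=True):
        c = compute_ducey_covariates(grp, **kwargs)
        rows.append(dict(plot_id=pid, occasion=occ, x0=c.x0, x1=c.x1, sg_bar=c.sg_bar))
    return pd.DataFrame(rows)


def fit_tree_level_frontier(
    covariates: pd.DataFrame,
    tau: float = 0.95,
    *,
    fit_random: bool = True,
    n_nodes: int = 15,
    seed: int = 0,
) -> TreeLevelFit:
    """tau-percentile mixed fit of the unit constraint 1 = a0 x0 + a1 x1 + u_i + e.

    Reuses the asymmetric-Laplace machinery of the static frontier module
    (response identically 1, no intercept, random plot intercept on the
    linear predictor). With the unit response on the *left*, the
    ``tau``-percentile density frontier corresponds to the ``1 - tau``
    quantile of the residual 1 - Xa: at the 95th percentile only 5% of
    stands are denser than the fitted frontier (a x > 1), so the ALD kernel
    is evaluated at 1 - tau internally. Collinear covariates (all specific
    gravities equal) are rejected with advice to drop to the
    single-covariate form.
    """
    if len(covariates) < 2:
        raise ValueError("need at least 2 plot-occasions")
    x0 = covariates["x0"].to_numpy(dtype=float)
    x1 = covariates["x1"].to_numpy(dtype=float)
    X = np.column_stack([x0, x1])
    sv = np.linalg.svd(X / np.linalg.norm(X, axis=0), compute_uv=False)
    if sv[-1] < 1e-10:
        raise ValueError(
            "x0 and x1 are collinear (all specific gravities equal); "
            "fit the single-covariate reduction on x0 instead"
        )
    y = np.ones(len(covariates))
    groups = covariates["plot_id"].to_numpy()
    # start near the uniform-stand solution 1 / (x0 + sg_bar x1) scale
    denom = float(np.median(x0))
    start = np.array([1.0 / (2 * denom), 1.0 / (2 * denom * max(float(covariates["sg_bar"].median()), 0.1)),
                      np.log(0.05), np.log(0.02)])
    out = fit_ald_mixed(y, X, groups, 1.0 - tau, fit_random=fit_random, n_nodes=n_nodes,
                        seed=seed, start=start if fit_random else start[:3])
    return TreeLevelFit(
        alpha0=float(out["beta"][0]),
        alpha1=float(out["beta"][1]),
        se_alpha0=float(out["se_beta"][0]),
        se_alpha1=float(out["se_beta"][1]),
        var_u0=out["var_u0"],
        loglik=out["loglik"],
        tau=tau,
        plot_effects=out["plot_effects"],
    )


def nmax_from_tree_fit(fit: TreeLevelFit | tuple[float, float], sg_bar: float) -> float:
    """Plot maximum density Nmax = 100 / (a0 + a1 SGbar), stems/ha."""
    if isinstance(fit, TreeLevelFit):
        a0, a1 = fit.alpha0, fit.alpha1
    else:
        a0, a1 = fit
    denom = a0 + a1 * sg_bar
    if denom <= 0:
        raise ValueError(f"a0 + a1*SGbar = {denom:.6g} is not positive; Nmax undefined")
    return SDI_SCALE / denom
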