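"""Self-thinning lines, carrying capacity, strategy comparison, capacity model.

Every fitted strategy is reduced to a common object: the self-thinning line
ln N = b0 + b1 ln dg. The reduction depends on the strategy:

* mean-regression fits (LME, LQMM) shift the intercept to the upper bound of
  its 95% confidence interval (b0 + 1.96 SE);
* the stochastic frontier already estimates the boundary (no shift);
* the mortality ODE's parameters give the attractor line in closed form;
* the trajectory model's reversed-Reineke part is inverted for N.

The line evaluated at a reference diameter (default 25.4 cm) gives the
maximum stand density index SDI_max = exp(b0 + b1 ln dbase) — the carrying
capacity proxy. Per-plot predicted random intercepts yield plot-level
capacities, which are compared across strategies with Scheffe's simultaneous
contrasts (compact letter display), and finally regressed on diversity and
climate covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

STRATEGIES = ("S-P-LME", "S-P-LQMM", "S-P-SFMM", "S-T-LME", "D-P-LME", "D-P-NBME", "D-P-NLME")

__all__ = [
    "ThinningLine",
    "CapacityEstimate",
    "CapacityModelFit",
    "line_from_upper_ci",
    "line_from_frontier",
    "line_from_ode_params",
    "line_from_trajectory",
    "predict_nmax",
    "capacity_table",
    "scheffe_compare",
    "compact_letter_display",
    "screen_bioclim",
    "fit_capacity_model",
    "STRATEGIES",
]


@dataclass(frozen=True)
class ThinningLine:
    strategy: str
    intercept: float  # b0, ln(stems/ha)
    slope: float  # b1, per ln cm
    provenance: str  # upper-CI | frontier | attractor | reversed-Reineke
    intercept_unshifted: float | None = None  # pre-CI-shift value when applicable


@dataclass(frozen=True)
class CapacityEstimate:
    plot_id: str
    strategy: str
    sdi_max: float  # stems/ha at dbase
    dbase: float = 25.4


@dataclass
class CapacityModelFit:
    terms: tuple[str, ...]
    theta: np.ndarray
    ses: np.ndarray
    sigma_e: float
    rmse: float
    rel_rmse: float  # percent of mean SDI_max
    bic: float
    r2: float
    pba_optimum: float | None  # -t1/(2 t2) when the quadratic opens downward
    result: object = None  # statsmodels results, for diagnostics


# --------------------------------------------------------------------------
# line derivations
# --------------------------------------------------------------------------

def _z_multiplier(alpha: float, exact_t: bool = False, df: int | None = None) -> float:
    if exact_t:
        if df is None:
            raise ValueError("exact t multiplier needs df")
        return float(stats.t.ppf(1 - alpha / 2, df))
    if alpha == 0.05:
        return 1.96  # conventional two-sided 5% multiplier, kept verbatim
    return float(stats.norm.ppf(1 - alpha / 2))


def line_from_upper_ci(fit, strategy: str, alpha: float = 0.05, *,
                       exact_t: bool = False, df: int | None = None) -> ThinningLine:
    """Shift the fitted intercept to the upper bound of its CI; slope unchanged."""
    se = getattr(fit, "se_beta0", None)
    if se is None or not np.isfinite(se):
        raise ValueError("fit carries no intercept SE; use the bootstrap SE option")
    b0 = float(fit.beta0)
    b1 = float(fit.beta1)
    mult = _z_multiplier(alpha, exact_t=exact_t, df=df)
    return ThinningLine(strategy=strategy, intercept=b0 + mult * float(se), slope=b1,
                        provenance="upper-CI", intercept_unshifted=b0)


def line_from_frontier(fit, strategy: str = "S-P-SFMM") -> ThinningLine:
    """The stochastic frontier Xb is itself the boundary (U >= 0): no shift."""
    return ThinningLine(strategy=strategy, intercept=float(fit.beta0), slope=float(fit.beta1),
                        provenance="frontier", intercept_unshifted=float(fit.beta0))


def line_from_ode_params(beta0: float, beta1: float, beta2: float,
                         strategy: str = "D-P-LME") -> ThinningLine:
    """Attractor line of dN/ddg = -e^b0 dg^b1 N^b2.

        slope     = (1 + b1) / (1 - b2)
        intercept = b0/(1 - b2) + (ln(b2 - 1) - ln(b1 + 1)) / (1 - b2)

    Requires b2 > 1 and b1 > -1 (finite attractor).
    """
    if not beta2 > 1:
        raise ValueError(f"beta2 = {beta2:.6g} violates beta2 > 1")
    if not beta1 > -1:
        raise ValueError(f"beta1 = {beta1:.6g} violates beta1 > -1")
    slope = (1.0 + beta1) / (1.0 - beta2)
    intercept = beta0 / (1.0 - beta2) + (np.log(beta2 - 1.0) - np.log(beta1 + 1.0)) / (1.0 - beta2)
    return ThinningLine(strategy=strategy, intercept=float(intercept), slope=float(slope),
                        provenance="attractor", intercept_unshifted=float(intercept))


def line_from_trajectory(fit, strategy: str = "D-P-NLME") -> ThinningLine:
    """Invert the reversed-Reineke part ln dg = a0 + a1 ln N for N."""
    a0 = float(fit.alpha0)
    a1 = float(fit.alpha1)
    if a1 == 0:
        raise ValueError("alpha1 = 0: trajectory line cannot be inverted for N")
    return ThinningLine(strategy=strategy, intercept=-a0 / a1, slope=1.0 / a1,
                        provenance="reversed-Reineke", intercept_unshifted=-a0 / a1)


def predict_nmax(line: ThinningLine, dbase: float = 25.4, plot_effect: float = 0.0) -> float:
    """Maximum density (stems/ha) the line permits at the reference diameter."""
    if not dbase > 0:
        raise ValueError("dbase must be positive")
    return float(np.exp(line.intercept + plot_effect + line.slope * np.log(dbase)))


def capacity_table(line: ThinningLine, plot_effects: dict[str, float] | None,
                   plot_ids, dbase: float = 25.4) -> pd.DataFrame:
    """Plot-level SDI_max for one strategy, using predicted random intercepts
    where the strategy has them (population line otherwise)."""
    rows = []
    effects = plot_effects or {}
    for pid in plot_ids:
        u = float(effects.get(str(pid), 0.0))
        rows.append(dict(plot_id=pid, strategy=line.strategy,
                         sdi_max=predict_nmax(line, dbase, u), dbase=dbase))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Scheffe comparison
# --------------------------------------------------------------------------

def scheffe_compare(estimates: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scheffe all-pairwise comparison of plot-level SDI_max by strategy.

    ``estimates`` needs columns strategy, sdi_max. Returns (letters table,
    contrast table). A contrast is significant when |difference| exceeds
    sqrt((k-1) F(alpha; k-1, N-k)) * SE(contrast), with SE from the pooled
    one-way-ANOVA mean square error. Letters come from the insert-and-absorb
    compact letter display.
    """
    groups = [g for g, _ in estimates.groupby("strategy", sort=False)]
    data = {g: sub["sdi_max"].to_numpy(dtype=float) for g, sub in estimates.groupby("strategy", sort=False)}
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 strategies")
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("need >= 2 estimates per strategy")
    N = sum(len(v) for v in data.values())
    means = {g: float(np.mean(v)) for g, v in data.items()}
    sse = sum(float(np.sum((v - means[g]) ** 2)) for g, v in data.items())
    df_err = N - k
    mse = sse / df_err
    if mse <= 0:
        raise ValueError("zero within-group variance everywhere: Scheffe test undefined")
    crit = np.sqrt((k - 1) * stats.f.ppf(1 - alpha, k - 1, df_err))

    rows = []
    sig = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = means[a] - means[b]
            se = np.sqrt(mse * (1.0 / len(data[a]) + 1.0 / len(data[b])))
            stat = abs(diff) / se
            pval = float(stats.f.sf(stat**2 / (k - 1), k - 1, df_err))
            significant = stat > crit
            sig[(a, b)] = sig[(b, a)] = significant
            rows.append(dict(strategy_a=a, strategy_b=b, diff=diff, se=se,
                             statistic=stat, critical=crit, p_value=pval,
                             significant=significant))
    contrasts = pd.DataFrame(rows)

    order = sorted(groups, key=lambda g: -means[g])
    letters = compact_letter_display(order, sig)
    table = pd.DataFrame(
        [dict(strategy=g, mean_sdi_max=means[g], n=len(data[g]), letters=letters[g]) for g in order]
    )
    return table, contrasts


def compact_letter_display(order: list[str], significant: dict) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    ``order`` lists the groups (typically by descending mean); ``significant``
    maps unordered pairs to True when the pair differs. Groups sharing a
    letter are not significantly different.
    """
    columns: list[set[str]] = [set(order)]
    # split any column containing a significantly different pair
    changed = True
    while changed:
        changed = False
        for col in list(columns):
            pair = next(
                ((a, b) for ai, a in enumerate(order) for b in order[ai + 1:]
                 if a in col and b in col and significant.get((a, b), False)),
                None,
            )
            if pair is None:
                continue
            a, b = pair
            col_a, col_b = col - {b}, col - {a}
            columns.remove(col)
            for new in (col_a, col_b):
                if not any(new <= other for other in columns):
                    columns.append(new)
            changed = True
            break
    # absorb: drop columns contained in others
    columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    out = {g: "" for g in order}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in order:
            if g in col:
                out[g] += letter
    return out


# --------------------------------------------------------------------------
# carrying-capacity model
# --------------------------------------------------------------------------

def screen_bioclim(capacity: pd.DataFrame, covariates: pd.DataFrame,
                   candidates: list[str] | None = None) -> pd.DataFrame:
    """Rank single-covariate linear models of SDI_max by BIC.

    ``capacity`` needs plot_id and sdi_max; ``covariates`` one row per plot.
    Constant candidates are skipped with a warning entry in the table.
    """
    merged = capacity.merge(covariates, on="plot_id")
    if candidates is None:
        candidates = [c for c in covariates.columns if c.startswith("bio")]
    rows = []
    y = merged["sdi_max"].to_numpy(dtype=float)
    for name in candidates:
        x = merged[name].to_numpy(dtype=float)
        if np.std(x) == 0 or not np.all(np.isfinite(x)):
            rows.append(dict(predictor=name, bic=np.inf, coef=np.nan, r2=np.nan,
                             note="skipped: constant or non-finite"))
            continue
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        rows.append(dict(predictor=name, bic=float(res.bic), coef=float(res.params[1]),
                         r2=float(res.rsquared), note=""))
    table = pd.DataFrame(rows).sort_values("bic", kind="stable").reset_index(drop=True)
    return table


def fit_capacity_model(
    capacity: pd.DataFrame,
    covariates: pd.DataFrame,
    terms: tuple[str, ...] = ("shannon", "bio14", "pba", "pba2"),
    *,
    standardize: bool = False,
) -> CapacityModelFit:
    """Least-squares carrying-capacity model SDI_max = f(theta, X) + e.

    ``terms`` name covariate columns; the special term "pba2" adds the square
    of "pba" (the quadratic successional-stage effect). Reports RMSE,
    relative RMSE (% of mean SDI_max), BIC, and the PBA optimum
    -t_pba / (2 t_pba2) when the quadratic opens downward.
    """
    merged = capacity.merge(covariates, on="plot_id")
    if len(merged) < len(terms) + 2:
        raise ValueError("too few plots for the requested model")
    y = merged["sdi_max"].to_numpy(dtype=float)
    cols = []
    names = []
    for t in terms:
        if t == "pba2":
            x = merged["pba"].to_numpy(dtype=float) ** 2
        else:
            x = merged[t].to_numpy(dtype=float)
        cols.append(x)
        names.append(t)
    X = np.column_stack(cols)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # identify aliased columns by dropping one at a time
        aliased = [names[j] for j in range(len(names))
                   if np.linalg.matrix_rank(np.delete(Xc, j + 1, axis=1)) == np.linalg.matrix_rank(Xc)]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = sm.OLS(y, Xc).fit()
    resid = res.resid
    rmse = float(np.sqrt(np.mean(resid**2)))
    rel = 100.0 * rmse / float(np.mean(y))
    pba_opt = None
    if "pba" in names and "pba2" in names and not standardize:
        t1 = float(res.params[1 + names.index("pba")])
        t2 = float(res.params[1 + names.index("pba2")])
        if t2 < 0:
            pba_opt = -t1 / (2.0 * t2)
    return CapacityModelFit(
        terms=tuple(["const"] + names),
        theta=np.asarray(res.params, dtype=float),
        ses=np.asarray(res.bse, dtype=float),
        sigma_e=float(np.sqrt(res.scale)),
        rmse=rmse,
        rel_rmse=rel,
        bic=float(res.bic),
        r2=float(res.rsquared),
        pba_optimum=pba_opt,
        result=res,
    )
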