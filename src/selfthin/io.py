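"""Readers/writers and the reproducible end-to-end pipeline.

Tables are plain CSV (UTF-8, header row) with floats serialized at 17
significant digits so a write/read round trip is lossless. Natural
logarithms are used throughout the package; :func:`ln` is the single shared
transform.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic_data import SimulationConfig, simulate_network
from .stand_metrics import validate_plot_table
from .static_frontier import fit_lme_reineke, fit_lqmm, fit_sfmm
from .tree_level import covariate_table, fit_tree_level_frontier
from .dynamic_models import (
    build_transitions,
    deaths_from_transitions,
    fit_density_model,
    fit_mortality_nbme,
    fit_trajectory_nlme,
)
from .thinning_capacity import (
    STRATEGIES,
    capacity_table,
    fit_capacity_model,
    line_from_frontier,
    line_from_ode_params,
    line_from_trajectory,
    line_from_upper_ci,
    predict_nmax,
    scheffe_compare,
    screen_bioclim,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

PLOT_COLUMNS = ["plot_id", "occasion", "area_m2", "n_ha", "dg_cm", "g_m2ha", "pba_pct"]
TREE_COLUMNS = ["plot_id", "occasion", "tree_id", "d_cm", "species", "sg", "ef"]


def ln(x):
    """Natural logarithm — the only log transform used anywhere in the package."""
    return np.log(x)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_plot_table(path) -> pd.DataFrame:
    """Read and validate a long-format plot table.

    Missing required columns raise naming them; rows with non-numeric or
    non-positive N/dg are rejected and logged, the rest kept. Adds an
    ``is_dynamic`` flag (>= 2 occasions) when absent.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot table {path} missing columns: {missing}")
    for col in ["occasion", "area_m2", "n_ha", "dg_cm", "g_m2ha", "pba_pct"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["n_ha", "dg_cm"]].isna().any(axis=1) | (df["n_ha"] <= 0) | (df["dg_cm"] <= 0)
    if bad.any():
        logger.warning("rejected %d invalid rows from %s", int(bad.sum()), path)
        df = df[~bad]
    df = df.reset_index(drop=True)
    if "is_dynamic" not in df.columns:
        df["is_dynamic"] = df.groupby("plot_id")["occasion"].transform("count") >= 2
    else:
        df["is_dynamic"] = df["is_dynamic"].astype(bool)
    issues = validate_plot_table(df, tol=1e-3)
    for _, row in issues.iterrows():
        logger.info("plot-table consistency: %s (%s)", row["issue"], row["plot_id"])
    return df


def read_tree_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tree table {path} missing columns: {missing}")
    for col in ["occasion", "tree_id", "d_cm", "sg", "ef"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["d_cm", "ef"]].isna().any(axis=1) | (df["d_cm"] <= 0) | (df["ef"] <= 0)
    if bad.any():
        logger.warning("rejected %d invalid tree rows from %s", int(bad.sum()), path)
        df = df[~bad]
    return df.reset_index(drop=True)


def read_covariates_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "plot_id" not in df.columns:
        raise ValueError(f"covariate table {path} missing columns: ['plot_id']")
    return df


# --------------------------------------------------------------------------
# run configuration and pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of an end-to-end run (simulate or read, fit, compare)."""

    simulate: SimulationConfig | None = None
    plot_table: str | None = None
    tree_table: str | None = None
    covariate_table: str | None = None
    strategies: tuple[str, ...] = STRATEGIES
    tau: float = 0.95
    dbase: float = 25.4
    alpha: float = 0.05
    seed: int = 20181111
    out_dir: str = "selfthin-out"
    static_only: bool = False  # True: static strategies see single-occasion plots only
    capacity_strategy: str = "S-P-LQMM"  # whose plot capacities feed the covariate model
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ValueError(f"unknown strategies: {unknown}; choose from {STRATEGIES}")
        if not self.dbase > 0:
            raise ValueError("dbase must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "strategies"},
                  **({"strategies": tuple(raw["strategies"])} if "strategies" in raw else {}))
        if sim is not None:
            for k in ("ode_params", "frontier", "dg_range", "dyn_dg0_range",
                      "dyn_start_offset", "dg_step_range", "area_range", "dyn_area_range"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            cfg.simulate = SimulationConfig(**sim)
        return cfg


def _fit_payload(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, pd.DataFrame):
            v = v.to_dict(orient="records")
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, dict):
            v = {k: (list(x) if isinstance(x, (tuple, np.ndarray)) else x) for k, x in v.items()}
        out[f.name] = v
    return out


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``config.out_dir``.

    Stages: obtain data (simulate or read) -> fit the requested strategies ->
    derive self-thinning lines -> plot-level capacities -> Scheffe comparison
    -> carrying-capacity covariate model. Stage failures are recorded in the
    manifest and later stages that can proceed still run. Fixed seed implies
    byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "selfthin_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
        "counts": {},
        "failures": {},
    }
    bundle: dict = {"manifest": manifest}

    # --- data -------------------------------------------------------------
    if config.simulate is not None:
        ds = simulate_network(config.simulate)
        plots, trees, covs, deaths = ds.plots, ds.trees, ds.covariates, ds.deaths
        write_table(plots, out_dir / "plots.csv")
        write_table(trees, out_dir / "trees.csv")
        write_table(covs, out_dir / "covariates.csv")
        write_table(deaths, out_dir / "deaths.csv")
    else:
        plots = read_plot_table(config.plot_table)
        trees = read_tree_table(config.tree_table) if config.tree_table else None
        covs = read_covariates_table(config.covariate_table) if config.covariate_table else None
        deaths = None
    manifest["counts"]["plot_rows"] = int(len(plots))
    manifest["counts"]["plots"] = int(plots["plot_id"].nunique())
    static_plots = plots[~plots["is_dynamic"]] if config.static_only else plots
    dyn_plots = plots[plots["is_dynamic"]]
    manifest["counts"]["static_rows_used"] = int(len(static_plots))
    manifest["counts"]["dynamic_rows"] = int(len(dyn_plots))

    fits: dict[str, object] = {}
    lines = []
    cap_frames = []

    def _stage(name, fn):
        try:
            fn()
            manifest["stages"][name] = "ok"
        except Exception as err:  # noqa: BLE001 - partial pipelines are a feature
            manifest["stages"][name] = "failed"
            manifest["failures"][name] = f"{type(err).__name__}: {err}"
            logger.warning("stage %s failed: %s", name, err)

    plot_ids = sorted(plots["plot_id"].unique())

    def _do_lme():
        fit = fit_lme_reineke(static_plots)
        fits["S-P-LME"] = fit
        line = line_from_upper_ci(fit, "S-P-LME", alpha=config.alpha)
        lines.append(line)
        lnb = np.log(config.dbase)
        effects = {pid: u0 + u1 * lnb for pid, (u0, u1) in fit.plot_effects.items()}
        cap_frames.append(capacity_table(line, effects, plot_ids, config.dbase))

    def _do_lqmm():
        fit = fit_lqmm(static_plots, tau=config.tau, seed=config.seed)
        fits["S-P-LQMM"] = fit
        line = line_from_upper_ci(fit, "S-P-LQMM", alpha=config.alpha)
        lines.append(line)
        cap_frames.append(capacity_table(line, fit.plot_effects, plot_ids, config.dbase))

    def _do_sfmm():
        fit = fit_sfmm(static_plots, seed=config.seed)
        fits["S-P-SFMM"] = fit
        line = line_from_frontier(fit, "S-P-SFMM")
        lines.append(line)
        cap_frames.append(capacity_table(line, fit.plot_effects, plot_ids, config.dbase))

    def _do_tree():
        if trees is None or len(trees) == 0:
            raise ValueError("no tree lists available")
        cov = covariate_table(trees)
        fit = fit_tree_level_frontier(cov, tau=config.tau, seed=config.seed)
        fits["S-T-LME"] = fit
        rows = []
        for _, r in cov.drop_duplicates("plot_id").iterrows():
            u = fit.plot_effects.get(str(r["plot_id"]), 0.0)
            denom = fit.alpha0 + fit.alpha1 * r["sg_bar"]
            if denom <= 0:
                continue
            rows.append(dict(plot_id=r["plot_id"], strategy="S-T-LME",
                             sdi_max=(1.0 - u) * 100.0 / denom, dbase=config.dbase))
        cap_frames.append(pd.DataFrame(rows))

    transitions = build_transitions(dyn_plots) if len(dyn_plots) else pd.DataFrame()

    def _do_density():
        if transitions.empty:
            raise ValueError("no dynamic transitions")
        fit = fit_density_model(transitions, seed=config.seed)
        fits["D-P-LME"] = fit
        line = line_from_ode_params(fit.beta0, fit.beta1, fit.beta2, "D-P-LME")
        lines.append(line)
        shift = 1.0 / (1.0 - fit.beta2)
        effects = {pid: eff.get("beta0", 0.0) * shift for pid, eff in fit.plot_effects.items()}
        cap_frames.append(capacity_table(line, effects, sorted(dyn_plots["plot_id"].unique()),
                                         config.dbase))

    def _do_nbme():
        if deaths is not None and len(deaths):
            dtab = deaths
        elif not transitions.empty:
            area = plots.drop_duplicates("plot_id").set_index("plot_id")["area_m2"]
            dtab = deaths_from_transitions(transitions, area.loc[transitions["plot_id"]].to_numpy())
        else:
            raise ValueError("no mortality data")
        fit = fit_mortality_nbme(dtab, seed=config.seed)
        fits["D-P-NBME"] = fit
        line = line_from_ode_params(fit.beta0, fit.beta1, fit.beta2, "D-P-NBME")
        lines.append(line)
        shift = 1.0 / (1.0 - fit.beta2)
        effects = {pid: u * shift for pid, u in fit.plot_effects.items()}
        cap_frames.append(capacity_table(line, effects, sorted(dtab["plot_id"].unique()),
                                         config.dbase))

    def _do_trajectory():
        if len(dyn_plots) == 0:
            raise ValueError("no dynamic plots")
        fit = fit_trajectory_nlme(dyn_plots, seed=config.seed)
        fits["D-P-NLME"] = fit
        line = line_from_trajectory(fit, "D-P-NLME")
        lines.append(line)
        # single population line: capacities vary only through each plot's
        # anchored trajectory evaluated at dbase (no random intercept case)
        cap_frames.append(capacity_table(line, None, sorted(dyn_plots["plot_id"].unique()),
                                         config.dbase))

    doers = {
        "S-P-LME": _do_lme, "S-P-LQMM": _do_lqmm, "S-P-SFMM": _do_sfmm,
        "S-T-LME": _do_tree, "D-P-LME": _do_density, "D-P-NBME": _do_nbme,
        "D-P-NLME": _do_trajectory,
    }
    for strat in config.strategies:
        if strat.startswith("D-") and transitions.empty:
            manifest["stages"][strat] = "skipped: no dynamic plots"
            continue
        _stage(strat, doers[strat])

    # --- outputs ----------------------------------------------------------
    fits_payload = {k: _fit_payload(v) for k, v in fits.items()}
    (out_dir / "fits.json").write_text(json.dumps(fits_payload, indent=2, sort_keys=True,
                                                  default=str))
    lines_df = pd.DataFrame(
        [dict(strategy=l.strategy, intercept=l.intercept, slope=l.slope,
              intercept_unshifted=l.intercept_unshifted, provenance=l.provenance,
              sdi_max_at_dbase=predict_nmax(l, config.dbase)) for l in lines]
    )
    write_table(lines_df, out_dir / "lines.csv")
    bundle["lines"] = lines_df
    bundle["fits"] = fits

    capacities = pd.concat(cap_frames, ignore_index=True) if cap_frames else pd.DataFrame(
        columns=["plot_id", "strategy", "sdi_max", "dbase"])
    bundle["capacities"] = capacities

    def _do_compare():
        table, contrasts = scheffe_compare(capacities, alpha=config.alpha)
        merged = table.merge(
            capacities.groupby("strategy")["sdi_max"].sem().rename("se"), on="strategy")
        write_table(merged, out_dir / "capacity.csv")
        write_table(contrasts, out_dir / "contrasts.csv")
        bundle["comparison"] = merged
        bundle["contrasts"] = contrasts

    if len(capacities) and capacities["strategy"].nunique() >= 2:
        _stage("compare", _do_compare)
    else:
        manifest["stages"]["compare"] = "skipped: < 2 strategies with capacities"
        write_table(capacities, out_dir / "capacity.csv")

    def _do_capacity_model():
        cap = capacities[capacities["strategy"] == config.capacity_strategy]
        if cap.empty or covs is None:
            raise ValueError("capacity model needs covariates and the chosen strategy's capacities")
        cov_model = covs.copy()
        pba = plots.sort_values("occasion").groupby("plot_id")["pba_pct"].last() / 100.0
        cov_model = cov_model.merge(pba.rename("pba"), on="plot_id")
        screening = screen_bioclim(cap, cov_model)
        write_table(screening, out_dir / "bioclim_screening.csv")
        fit = fit_capacity_model(cap, cov_model)
        report = {
            "terms": list(fit.terms),
            "theta": fit.theta.tolist(),
            "ses": fit.ses.tolist(),
            "rmse": fit.rmse,
            "rel_rmse_pct": fit.rel_rmse,
            "bic": fit.bic,
            "r2": fit.r2,
            "pba_optimum": fit.pba_optimum,
            "best_single_bioclim": screening.iloc[0]["predictor"],
        }
        (out_dir / "capacity_model.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out_dir / "capacity_model.txt").write_text(_capacity_report_text(report))
        bundle["capacity_model"] = fit
        bundle["screening"] = screening

    _stage("capacity_model", _do_capacity_model)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # manifests of identical runs must not differ by location
    if d.get("simulate") is not None:
        d["simulate"] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in d["simulate"].items()}
    d["strategies"] = list(d["strategies"])
    return d


def _capacity_report_text(report: dict) -> str:
    lines = ["carrying-capacity model", "======================="]
    for t, th, se in zip(report["terms"], report["theta"], report["ses"]):
        lines.append(f"  {t:>10s}  {th:12.5g}  (se {se:.5g})")
    lines.append(f"  RMSE {report['rmse']:.4g} stems/ha ({report['rel_rmse_pct']:.2f}% of mean)")
    lines.append(f"  BIC {report['bic']:.4g}   R^2 {report['r2']:.4f}")
    if report.get("pba_optimum") is not None:
        lines.append(f"  PBA optimum {100 * report['pba_optimum']:.1f}% basal-area share")
    lines.append(f"  best single bioclim predictor: {report['best_single_bioclim']}")
    return "\n".join(lines) + "\n"
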