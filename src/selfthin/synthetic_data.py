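"""Synthetic plot network generator.

The field data behind self-thinning studies of this kind (long-term permanent
plots in mixed *Nothofagus* forest) are rarely deposited, so every estimation
strategy in this package is exercised against a simulated plot network whose
generative structure is exactly the structure the fitters assume:

* a log-linear size-density frontier ln N = b0 + b1 ln dg (Reineke form);
* **static plots**: one occasion each, scattered below the frontier with a
  truncated-exponential frontier gap on the log scale (frontier data are
  one-sided, which keeps the 0.95 quantile estimable);
* **dynamic plots**: remeasured trajectories obeying the mortality ODE
  dN/ddg = -exp(b0) dg^b1 N^b2, integrated in closed form, with a plot-level
  Gaussian random effect on the ODE intercept and multiplicative lognormal
  observation noise on recorded N;
* **death counts** between occasions drawn negative-binomial with mean equal
  to the Euler step of the ODE (the log-link mortality model's mean function)
  and dispersion theta;
* **tree lists** (Weibull-like diameters above the 5 cm calliper limit,
  species mixture with fixed wood specific gravities) constructed so the
  plot-level aggregation reproduces each occasion's recorded N and dg;
* **site covariates** (elevation, aspect, slope, bio1..bio19) where the
  Shannon diversity of the plot's species mix and "bio14" (precipitation of
  the driest month) shift the plot's frontier offset with configurable
  effect sizes.

Random-effect and observation-noise draws are truncated at +-3 sd so that all
simulated points provably stay below the generating frontier plus 3 combined
sd on the log scale. One master seed spawns independent per-component streams;
regenerating with the same config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stand_metrics import BASAL_AREA_FACTOR

#: species codes and wood specific gravities used in simulated tree lists;
#: first three are the primary (Nothofagus) species.
SPECIES_SG = {
    "NOB": 0.58,  # N. obliqua (roble)
    "NAL": 0.55,  # N. alpina (rauli)
    "NDO": 0.53,  # N. dombeyi (coigue)
    "LAU": 0.45,  # laurel-type companion
    "OTR": 0.48,  # other companions
}
PRIMARY_CODES = ("NOB", "NAL", "NDO")

#: rough location/scale (long-term means) for the 19 bioclim variables
_BIOCLIM_LOC = {
    "bio1": 11.0, "bio2": 10.5, "bio3": 45.0, "bio4": 380.0, "bio5": 24.0,
    "bio6": 1.5, "bio7": 22.0, "bio8": 7.0, "bio9": 16.0, "bio10": 16.5,
    "bio11": 6.5, "bio12": 1700.0, "bio13": 280.0, "bio14": 60.0,
    "bio15": 60.0, "bio16": 760.0, "bio17": 230.0, "bio18": 240.0, "bio19": 720.0,
}
_BIOCLIM_SCALE = {
    "bio1": 1.5, "bio2": 1.0, "bio3": 3.0, "bio4": 40.0, "bio5": 1.8,
    "bio6": 1.2, "bio7": 2.0, "bio8": 1.5, "bio9": 2.0, "bio10": 1.6,
    "bio11": 1.4, "bio12": 350.0, "bio13": 60.0, "bio14": 25.0,
    "bio15": 10.0, "bio16": 160.0, "bio17": 60.0, "bio18": 60.0, "bio19": 150.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic plot network.

    Defaults emulate the marginal structure of the motivating plot network:
    130 plots of which one fifth are remeasured, stem densities within the
    330-3,580 (static) and 670-4,680 (dynamic) stems/ha envelopes, quadratic
    mean diameters in the mid-teens to high-forties (cm), and 2-5 cm of dg
    growth per remeasurement period. The ODE parameters are chosen so the
    trajectory attractor coincides with the static generating frontier
    (intercept 12.15, slope -1.55 — a Reineke-like slope).
    """

    n_plots: int = 130
    prop_dynamic: float = 0.2
    occasions_per_dynamic: int = 3
    # mortality ODE dN/ddg = -exp(b0) dg^b1 N^b2; attractor == frontier below
    ode_params: tuple[float, float, float] = (np.log(1.55) - 12.15, 0.55, 2.0)
    frontier: tuple[float, float] = (12.15, -1.55)
    re_sd: float = 0.06  # plot random-intercept sd (on the ODE intercept scale)
    obs_sd: float = 0.03  # lognormal observation noise sd on ln N
    nb_theta: float = 30.0  # negative-binomial dispersion of death counts
    dg_range: tuple[float, float] = (14.0, 46.0)  # static plots, cm
    dyn_dg0_range: tuple[float, float] = (14.0, 20.0)  # dynamic first occasion
    dyn_start_offset: tuple[float, float] = (-0.45, 0.0)  # lnN offset from attractor
    dg_step_range: tuple[float, float] = (2.0, 5.0)  # cm growth per period
    gap_scale: float = 0.45  # truncated-exponential frontier gap, log scale
    gap_min: float = 0.08
    gap_max: float = 1.2
    n_floor: float = 380.0  # stems/ha; gap truncated so statics stay above
    area_range: tuple[float, float] = (500.0, 2000.0)  # m^2 (static plots)
    dyn_area_range: tuple[float, float] = (5000.0, 10000.0)  # m^2
    bio14_effect: float = 0.08  # frontier-offset shift per sd of bio14
    shannon_effect: float = 0.05  # frontier-offset shift per sd of Shannon H
    seed: int = 20181111

    def validate(self) -> None:
        b0, b1, b2 = self.ode_params
        if not (b2 > 1 and b1 > -1):
            raise ValueError("ode_params need beta2 > 1 and beta1 > -1 for a finite attractor")
        if not 0.0 <= self.prop_dynamic <= 1.0:
            raise ValueError("prop_dynamic must be in [0, 1]")
        if self.occasions_per_dynamic < 2:
            raise ValueError("dynamic plots need >= 2 occasions")
        if self.nb_theta <= 0:
            raise ValueError("nb_theta must be positive")


@dataclass
class SyntheticDataset:
    """Simulated plot network plus the generating truth."""

    plots: pd.DataFrame  # plot_id, occasion, area_m2, n_ha, dg_cm, g_m2ha, pba_pct, is_dynamic
    trees: pd.DataFrame  # plot_id, occasion, tree_id, d_cm, species, sg, ef
    covariates: pd.DataFrame  # plot_id, elevation, aspect, slope, shannon, richness, bio1..bio19
    deaths: pd.DataFrame  # plot_id, occ0, occ1, area_m2, n0_ha, dg0_cm, dg1_cm, deaths_count
    truth: dict


def simulate_trajectory(ode_params, N0: float, dg_grid) -> np.ndarray:
    """Density along the closed-form solution of dN/ddg = -e^b0 dg^b1 N^b2.

    For b2 != 1 the solution through (dg_0, N_0) is

        ln N_1 = (1/(1-b2)) ln[ N_0^(1-b2)
                 + e^b0 ((1-b2)/(b1+1)) (dg_0^(b1+1) - dg_1^(b1+1)) ]

    evaluated sequentially along the strictly increasing ``dg_grid`` (the
    first grid point carries N0). Raises if the bracket goes non-positive,
    i.e. the population goes extinct before reaching that diameter.
    """
    b0, b1, b2 = (float(v) for v in ode_params)
    dg = np.asarray(dg_grid, dtype=float)
    if dg.ndim != 1 or dg.size < 1:
        raise ValueError("dg_grid must be a 1-D array of diameters")
    if np.any(np.diff(dg) <= 0):
        raise ValueError("dg_grid must be strictly increasing")
    if not N0 > 0:
        raise ValueError("N0 must be positive")
    if b2 == 1.0:
        raise ValueError("beta2 = 1 is a degenerate (log-linear) case not supported")
    p = b1 + 1.0
    q = 1.0 - b2
    bracket = N0**q + np.exp(b0) * (q / p) * (dg[0] ** p - dg**p)
    bad = bracket <= 0
    if np.any(bad):
        k = int(np.argmax(bad))
        raise ValueError(
            f"trajectory extinct before dg = {dg[k]:.3f} cm (grid step {k}): "
            "closed-form bracket non-positive"
        )
    out = np.exp(np.log(bracket) / q)
    out[0] = N0  # the first grid point carries the initial density exactly
    return out


def _truncnorm(rng: np.random.Generator, sd: float, size=None) -> np.ndarray:
    """Gaussian draws clipped at +-3 sd (keeps frontier containment provable)."""
    if sd > 0:
        return np.clip(rng.normal(0.0, sd, size=size), -3.0 * sd, 3.0 * sd)
    return np.zeros(size if size is not None else ())


def _draw_tree_list(rng: np.random.Generator, n_ha: float, dg: float, area_m2: float,
                    species_probs: np.ndarray) -> pd.DataFrame:
    """Tree list reproducing (n_ha, dg) exactly for an (adjusted) fixed-area plot.

    Diameters are 5 + s*W with W Weibull(k=2.3); s solves the quadratic that
    pins the sample quadratic mean at dg, so every diameter respects the 5 cm
    calliper limit. The plot area is nudged so EF = 10000/area = n_ha/m with
    an integer tree count m.
    """
    m = max(20, int(round(n_ha * area_m2 / 10000.0)))
    w = rng.weibull(2.3, size=m)
    w = np.maximum(w, 1e-3)
    # solve 25 + 10 s mean(w) + s^2 mean(w^2) = dg^2 for s > 0
    a, b, c = float(np.mean(w**2)), 10.0 * float(np.mean(w)), 25.0 - dg**2
    s = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    d = 5.0 + s * w
    ef = n_ha / m
    species = rng.choice(list(SPECIES_SG), size=m, p=species_probs)
    return pd.DataFrame(
        {
            "tree_id": np.arange(1, m + 1),
            "d_cm": d,
            "species": species,
            "sg": [SPECIES_SG[sp] for sp in species],
            "ef": ef,
        }
    )


def attractor_line(ode_params) -> tuple[float, float]:
    """(intercept, slope) of the self-thinning attractor implied by the ODE."""
    b0, b1, b2 = ode_params
    slope = (1.0 + b1) / (1.0 - b2)
    intercept = b0 / (1.0 - b2) + (np.log(b2 - 1.0) - np.log(b1 + 1.0)) / (1.0 - b2)
    return float(intercept), float(slope)


def simulate_network(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic plot network described in the module docstring."""
    config.validate()
    b0f, b1f = config.frontier
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_cov, rng_static, rng_dyn, rng_trees, rng_deaths, rng_noise = (
        np.random.default_rng(s) for s in streams
    )

    n_dyn = int(round(config.n_plots * config.prop_dynamic))
    n_static = config.n_plots - n_dyn
    plot_ids = [f"P{i:04d}" for i in range(1, config.n_plots + 1)]
    is_dyn = np.array([i < n_dyn for i in range(config.n_plots)])

    # --- covariates first (they shift frontier offsets) -------------------
    cov_rows = []
    species_probs = np.empty((config.n_plots, len(SPECIES_SG)))
    for i, pid in enumerate(plot_ids):
        # Nothofagus share high (successional forests), companions minor
        noth = rng_cov.dirichlet([6.0, 3.0, 2.0])
        comp = rng_cov.dirichlet([1.5, 1.5])
        noth_share = rng_cov.beta(8.0, 2.2)  # mean ~0.78, range well spread
        probs = np.concatenate([noth * noth_share, comp * (1 - noth_share)])
        species_probs[i] = probs
        shannon = float(-(probs[probs > 0] * np.log(probs[probs > 0])).sum())
        row = {
            "plot_id": pid,
            "elevation": float(rng_cov.uniform(150.0, 1100.0)),
            "aspect": float(rng_cov.uniform(0.0, 360.0)),
            "slope": float(rng_cov.uniform(0.0, 60.0)),
            "shannon": shannon,
            "richness": int((probs > 0.01).sum()),
        }
        for k in _BIOCLIM_LOC:
            row[k] = float(rng_cov.normal(_BIOCLIM_LOC[k], _BIOCLIM_SCALE[k]))
        cov_rows.append(row)
    covariates = pd.DataFrame(cov_rows)

    z_bio14 = (covariates["bio14"] - covariates["bio14"].mean()) / covariates["bio14"].std()
    z_shan = (covariates["shannon"] - covariates["shannon"].mean()) / covariates["shannon"].std()
    # favourable sites (wet dry-season, diverse) sit closer to the frontier
    offset_shift = (config.bio14_effect * z_bio14 + config.shannon_effect * z_shan).to_numpy()

    plot_rows: list[dict] = []
    tree_frames: list[pd.DataFrame] = []
    death_rows: list[dict] = []
    frontier_gap = np.full(config.n_plots, np.nan)

    # --- static plots -----------------------------------------------------
    for i in range(n_dyn, config.n_plots):
        pid = plot_ids[i]
        dg = float(rng_static.uniform(*config.dg_range))
        f_ln = b0f + b1f * np.log(dg)
        hi = min(config.gap_max, f_ln - np.log(config.n_floor))
        gap = config.gap_min + rng_static.exponential(config.gap_scale)
        gap = gap - offset_shift[i]
        gap = float(np.clip(gap, config.gap_min, max(config.gap_min, hi)))
        frontier_gap[i] = gap
        eps = float(_truncnorm(rng_noise, config.obs_sd, size=1)[0])
        n_ha = float(np.exp(f_ln - gap + eps))
        area = float(rng_static.uniform(*config.area_range))
        trees = _draw_tree_list(rng_trees, n_ha, dg, area, species_probs[i])
        trees.insert(0, "occasion", 0)
        trees.insert(0, "plot_id", pid)
        g = float((trees["ef"] * BASAL_AREA_FACTOR * trees["d_cm"] ** 2).sum())
        primary = trees["species"].isin(PRIMARY_CODES)
        pba = 100.0 * float((trees.loc[primary, "ef"] * BASAL_AREA_FACTOR * trees.loc[primary, "d_cm"] ** 2).sum()) / g
        plot_rows.append(
            dict(plot_id=pid, occasion=0, area_m2=10000.0 / trees["ef"].iloc[0],
                 n_ha=n_ha, dg_cm=dg, g_m2ha=g, pba_pct=pba, is_dynamic=False)
        )
        tree_frames.append(trees)

    # --- dynamic plots ----------------------------------------------------
    ob0, ob1, ob2 = config.ode_params
    for i in range(n_dyn):
        pid = plot_ids[i]
        u_i = float(_truncnorm(rng_dyn, config.re_sd, size=1)[0])
        ode_i = (ob0 + u_i, ob1, ob2)
        a_int, a_slo = attractor_line(ode_i)
        dg0 = float(rng_dyn.uniform(*config.dyn_dg0_range))
        steps = np.clip(
            rng_dyn.lognormal(np.log(3.0), 0.25, size=config.occasions_per_dynamic - 1),
            *config.dg_step_range,
        )
        dg_grid = dg0 + np.concatenate([[0.0], np.cumsum(steps)])
        start = float(rng_dyn.uniform(*config.dyn_start_offset))
        # dynamic plots start essentially on their own attractor; the covariate
        # shift acts through the static frontier gaps only
        n0 = float(np.exp(a_int + a_slo * np.log(dg0) + start))
        frontier_gap[i] = -start
        n_latent = simulate_trajectory(ode_i, n0, dg_grid)
        eps = _truncnorm(rng_noise, config.obs_sd, size=len(dg_grid))
        n_obs = n_latent * np.exp(eps)
        area = float(rng_dyn.uniform(*config.dyn_area_range))
        for j, (dg_j, n_j) in enumerate(zip(dg_grid, n_obs)):
            trees = _draw_tree_list(rng_trees, float(n_j), float(dg_j), area, species_probs[i])
            trees.insert(0, "occasion", j)
            trees.insert(0, "plot_id", pid)
            g = float((trees["ef"] * BASAL_AREA_FACTOR * trees["d_cm"] ** 2).sum())
            primary = trees["species"].isin(PRIMARY_CODES)
            pba = 100.0 * float(
                (trees.loc[primary, "ef"] * BASAL_AREA_FACTOR * trees.loc[primary, "d_cm"] ** 2).sum()
            ) / g
            plot_rows.append(
                dict(plot_id=pid, occasion=j, area_m2=10000.0 / trees["ef"].iloc[0],
                     n_ha=float(n_j), dg_cm=float(dg_j), g_m2ha=g, pba_pct=pba, is_dynamic=True)
            )
            tree_frames.append(trees)
        # death counts: NB around the Euler step of the ODE (log-link mean)
        for j in range(len(dg_grid) - 1):
            ddg = dg_grid[j + 1] - dg_grid[j]
            mu_ha = np.exp(ob0 + u_i) * dg_grid[j] ** ob1 * n_latent[j] ** ob2 * ddg
            mu_cnt = mu_ha * area / 10000.0
            deaths = int(rng_deaths.negative_binomial(config.nb_theta,
                                                      config.nb_theta / (config.nb_theta + mu_cnt)))
            death_rows.append(
                dict(plot_id=pid, occ0=j, occ1=j + 1, area_m2=area,
                     n0_ha=float(n_latent[j]), dg0_cm=float(dg_grid[j]),
                     dg1_cm=float(dg_grid[j + 1]), deaths_count=deaths)
            )

    plots = pd.DataFrame(plot_rows).sort_values(["plot_id", "occasion"]).reset_index(drop=True)
    trees = pd.concat(tree_frames, ignore_index=True) if tree_frames else pd.DataFrame(
        columns=["plot_id", "occasion", "tree_id", "d_cm", "species", "sg", "ef"]
    )
    trees = trees.sort_values(["plot_id", "occasion", "tree_id"]).reset_index(drop=True)
    deaths = pd.DataFrame(
        death_rows,
        columns=["plot_id", "occ0", "occ1", "area_m2", "n0_ha", "dg0_cm", "dg1_cm", "deaths_count"],
    )
    truth = {
        "config": asdict(config),
        "frontier": tuple(config.frontier),
        "ode_params": tuple(config.ode_params),
        "attractor": attractor_line(config.ode_params),
        "frontier_gap": dict(zip(plot_ids, frontier_gap.tolist())),
    }
    return SyntheticDataset(plots=plots, trees=trees, covariates=covariates, deaths=deaths, truth=truth)


def simulate_nb_transitions(coeffs, theta: float, n: int, seed: int,
                            dg0_range=(12.0, 30.0), n0_range=(800.0, 4000.0),
                            ddg_range=(2.0, 5.0), area_m2: float = 10000.0,
                            n_per_plot: int = 1, re_sd: float = 0.0) -> pd.DataFrame:
    """Transitions with NB death counts from the log-link mean.

    ln mu = b0 [+ u_i] + b1 ln dg0 + b2 ln N0 + ln(ddg), counts at the given
    plot area. ``n`` plots contribute ``n_per_plot`` transitions each, sharing
    a Gaussian plot intercept of sd ``re_sd``; used for mortality-model
    parameter-recovery checks.
    """
    b0, b1, b2 = coeffs
    rng = np.random.default_rng(seed)
    m = n * n_per_plot
    plot = np.repeat([f"T{i:05d}" for i in range(n)], n_per_plot)
    u = np.repeat(rng.normal(0.0, re_sd, size=n) if re_sd > 0 else np.zeros(n), n_per_plot)
    dg0 = rng.uniform(*dg0_range, size=m)
    n0 = rng.uniform(*n0_range, size=m)
    ddg = rng.uniform(*ddg_range, size=m)
    mu_ha = np.exp(b0 + u) * dg0**b1 * n0**b2 * ddg
    mu_cnt = mu_ha * area_m2 / 10000.0
    deaths = rng.negative_binomial(theta, theta / (theta + mu_cnt))
    return pd.DataFrame(
        {
            "plot_id": plot,
            "occ0": np.tile(np.arange(n_per_plot), n),
            "occ1": np.tile(np.arange(n_per_plot), n) + 1,
            "area_m2": area_m2,
            "n0_ha": n0, "dg0_cm": dg0, "dg1_cm": dg0 + ddg,
            "deaths_count": deaths,
        }
    )
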