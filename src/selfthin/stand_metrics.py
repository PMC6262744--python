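"""Plot-level stand variables and diversity/structure summaries from tree lists.

A tree list is the per-tree measurement record of a fixed-area plot: diameter at
breast height (d, cm; protocol floor 5 cm), species code, wood specific gravity
(SG), and an expansion factor (EF, trees/ha) converting the sampled tree to a
per-hectare density contribution (EF = 10000 / plot area for fixed-area plots).

From a tree list the stand variables are

    N  = sum EF                              stems/ha
    G  = sum EF * (pi/40000) * d^2           basal area, m^2/ha
    dg = sqrt(sum EF d^2 / sum EF)           quadratic mean diameter, cm
    PBA = 100 * G(primary species) / G       % basal area of the primary genus

PBA is a successional-stage proxy: the share of stand basal area held by the
pioneer (here *Nothofagus*) species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: species codes treated as the primary (pioneer) genus unless overridden;
#: the three Nothofagus species of the roble-rauli-coigue forest type.
DEFAULT_PRIMARY_SPECIES = frozenset({"NOB", "NAL", "NDO"})

BASAL_AREA_FACTOR = math.pi / 40000.0  # d in cm -> m^2 of stem cross-section


@dataclass(frozen=True)
class TreeRecord:
    """One measured tree on one plot occasion."""

    plot_id: str
    occasion: int
    diameter: float  # cm, >= 5 by measurement protocol
    species: str
    specific_gravity: float  # dimensionless, in (0, 1.5)
    expansion_factor: float  # trees/ha, > 0

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"non-positive diameter {self.diameter!r}")
        if not self.expansion_factor > 0:
            raise ValueError(f"non-positive expansion factor {self.expansion_factor!r}")


@dataclass(frozen=True)
class PlotMeasurement:
    """One plot x occasion record of stand variables."""

    plot_id: str
    occasion: int
    N: float  # stems/ha
    dg: float  # cm
    G: float  # m^2/ha
    PBA: float  # percent in [0, 100]
    is_dynamic: bool = False


@dataclass
class DiameterStats:
    """Expansion-factor-weighted summaries of the diameter distribution."""

    d_min: float
    d_max: float
    median: float
    sd: float | None
    cv: float | None  # percent
    skewness: float | None


@dataclass
class SiteCovariates:
    """Per-plot site descriptors used in the carrying-capacity model."""

    plot_id: str
    elevation: float  # m
    aspect: float  # degrees [0, 360)
    slope: float  # percent
    bioclim: dict[str, float] = field(default_factory=dict)  # bio1..bio19
    shannon: float = 0.0  # nats
    richness: int = 1
    diam_stats: DiameterStats | None = None


def _as_tree_arrays(trees) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if len(trees) == 0:
        raise ValueError("no trees")
    d = np.asarray([t.diameter for t in trees], dtype=float)
    ef = np.asarray([t.expansion_factor for t in trees], dtype=float)
    sg = np.asarray([t.specific_gravity for t in trees], dtype=float)
    sp = np.asarray([t.species for t in trees], dtype=object)
    if np.any(d <= 0):
        raise ValueError("non-positive diameter in tree list")
    return d, ef, sg, sp


def compute_stand_variables(
    trees: list[TreeRecord],
    primary_species: frozenset[str] | set[str] = DEFAULT_PRIMARY_SPECIES,
) -> PlotMeasurement:
    """Aggregate a single plot-occasion tree list to stand variables.

    All trees must share plot_id and occasion. PBA is the basal-area share of
    ``primary_species``.
    """
    d, ef, _, sp = _as_tree_arrays(trees)
    ids = {(t.plot_id, t.occasion) for t in trees}
    if len(ids) != 1:
        raise ValueError(f"tree list mixes plot-occasions: {sorted(ids)}")
    plot_id, occasion = next(iter(ids))

    n = float(ef.sum())
    g_tree = ef * BASAL_AREA_FACTOR * d**2
    g = float(g_tree.sum())
    dg = float(np.sqrt((ef * d**2).sum() / n))
    primary = np.isin(sp, list(primary_species))
    pba = min(100.0, max(0.0, 100.0 * float(g_tree[primary].sum()) / g))
    return PlotMeasurement(plot_id=plot_id, occasion=occasion, N=n, dg=dg, G=g, PBA=pba)


def shannon_index(abundance) -> float:
    """Shannon diversity H = -sum p_s ln p_s (nats) from counts or proportions.

    Accepts a mapping species -> abundance or a sequence of abundances; zero
    abundances are dropped.
    """
    if hasattr(abundance, "values") and not isinstance(abundance, (pd.Series, np.ndarray)):
        vals = np.asarray(list(abundance.values()), dtype=float)
    else:
        vals = np.asarray(abundance, dtype=float)
    if vals.size == 0:
        raise ValueError("no species")
    if np.any(vals < 0):
        raise ValueError("negative abundance")
    total = vals.sum()
    if total <= 0:
        raise ValueError("all-zero abundances")
    p = vals[vals > 0] / total
    return float(-(p * np.log(p)).sum())


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    # step-function (frequency-weight) quantile: agrees with replicating each
    # tree in proportion to its expansion factor
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cum, q, side="left")])


def diameter_distribution_stats(trees: list[TreeRecord]) -> DiameterStats:
    """EF-weighted min/max/median/sd/cv/skewness of the diameter distribution.

    Weighted moments treat expansion factors as frequency weights. The sd and
    skewness use the population (biased) estimators; with fewer than 2 (sd/cv)
    or 3 (skewness) trees the statistic is reported as None rather than raised.
    Degenerate distributions (all diameters equal) report skewness 0.
    """
    d, ef, _, _ = _as_tree_arrays(trees)
    w = ef / ef.sum()
    mean = float((w * d).sum())
    out = DiameterStats(
        d_min=float(d.min()),
        d_max=float(d.max()),
        median=_weighted_quantile(d, ef, 0.5),
        sd=None,
        cv=None,
        skewness=None,
    )
    if d.size >= 2:
        var = float((w * (d - mean) ** 2).sum())
        out.sd = math.sqrt(var)
        out.cv = 100.0 * out.sd / mean if mean > 0 else None
    if d.size >= 3:
        if out.sd == 0:
            out.skewness = 0.0
        else:
            m3 = float((w * (d - mean) ** 3).sum())
            out.skewness = m3 / out.sd**3
    return out


def validate_plot_table(plots: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Flag internal inconsistencies in a long-format plot table.

    Checks the G = (pi/40000) dg^2 N identity (when all three columns present)
    and that dg is non-decreasing across occasions within a plot. Returns a
    DataFrame of violations (empty when clean); never raises.
    """
    issues = []
    if {"n_ha", "dg_cm", "g_m2ha"}.issubset(plots.columns):
        g_implied = BASAL_AREA_FACTOR * plots["dg_cm"] ** 2 * plots["n_ha"]
        bad = (g_implied - plots["g_m2ha"]).abs() > tol * np.maximum(1.0, plots["g_m2ha"].abs())
        for idx in plots.index[bad]:
            issues.append((plots.at[idx, "plot_id"], plots.at[idx, "occasion"], "G-dg-N identity violated"))
    for pid, grp in plots.sort_values("occasion").groupby("plot_id"):
        dg = grp["dg_cm"].to_numpy()
        if np.any(np.diff(dg) < 0):
            issues.append((pid, None, "dg decreasing across occasions"))
    return pd.DataFrame(issues, columns=["plot_id", "occasion", "issue"])
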