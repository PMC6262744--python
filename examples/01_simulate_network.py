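"""Generate the synthetic plot network and look at its structure.

The generator emulates a long-term permanent-plot network in mixed forest:
single-occasion ("static") plots scattered below a Reineke frontier
ln N = 12.15 - 1.55 ln dg, and remeasured ("dynamic") plots whose density
declines along the mortality ODE dN/ddg = -e^b0 dg^b1 N^b2, plus tree lists
and site covariates.
"""

from selfthin import SimulationConfig, simulate_network

ds = simulate_network(SimulationConfig(seed=20181111))

static = ds.plots[~ds.plots["is_dynamic"]]
dynamic = ds.plots[ds.plots["is_dynamic"]]
print(f"plots: {ds.plots['plot_id'].nunique()} "
      f"({static['plot_id'].nunique()} static, {dynamic['plot_id'].nunique()} dynamic; "
      f"{len(ds.plots)} plot-occasions)")
print(f"trees measured: {len(ds.trees)}")
print("static density range  [stems/ha]:",
      f"{static['n_ha'].min():.0f} - {static['n_ha'].max():.0f}")
print("dynamic density range [stems/ha]:",
      f"{dynamic['n_ha'].min():.0f} - {dynamic['n_ha'].max():.0f}")
print("generating frontier:", ds.truth["frontier"])
print("ODE attractor (should equal the frontier):",
      tuple(round(v, 4) for v in ds.truth["attractor"]))
# The attractor line is where self-thinning stands end up: density at any
# quadratic mean diameter dg is bounded by exp(12.15 - 1.55 ln dg).
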