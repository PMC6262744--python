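"""Tree-level additive stand-density frontier (wood-density aware).

Instead of plot totals, each tree contributes EF * (d/25.4)^1.6 / 100 to a
stand density index x0, and the same weighted by wood specific gravity to
x1. Fitting the unit constraint a0 x0 + a1 x1 = 1 at the 95th percentile
gives a frontier in which denser-wooded stands saturate at fewer stems:
Nmax = 100 / (a0 + a1 * SGbar).
"""

from selfthin import SimulationConfig, simulate_network
from selfthin.tree_level import covariate_table, fit_tree_level_frontier, nmax_from_tree_fit

ds = simulate_network(SimulationConfig(seed=20181111))
cov = covariate_table(ds.trees)
print(cov.head(3).to_string(index=False))

fit = fit_tree_level_frontier(cov, tau=0.95, seed=0)
print(f"\nalpha0 = {fit.alpha0:.5f} (se {fit.se_alpha0:.5f})")
print(f"alpha1 = {fit.alpha1:.5f} (se {fit.se_alpha1:.5f})")

for sg in (0.45, 0.55, 0.65):
    print(f"Nmax at mean specific gravity {sg:.2f}: "
          f"{nmax_from_tree_fit(fit, sg):7.0f} stems/ha")
# The sign of alpha1 decides how maximum density responds to the stand's
# average wood specific gravity (positive: heavier-wooded stands saturate at
# fewer stems). In this synthetic network species mixture is independent of
# the frontier, so the fitted SG effect reflects sampling noise rather than
# a real trait gradient.
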