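"""Fit the three static site-level frontier strategies and derive their lines.

All three model ln N = b0 + b1 ln dg on plot measurements; they differ in how
they turn a cloud of understocked-to-full stands into a *frontier*:
the LME shifts its mean intercept to the upper 95% confidence bound, the
LQMM fits the 0.95 conditional quantile directly, and the stochastic
frontier model treats the distance below the line as a one-sided error.
"""

from selfthin import SimulationConfig, simulate_network
from selfthin.static_frontier import fit_lme_reineke, fit_lqmm, fit_sfmm, select_quantile
from selfthin.thinning_capacity import line_from_frontier, line_from_upper_ci, predict_nmax

ds = simulate_network(SimulationConfig(seed=20181111))

lme = fit_lme_reineke(ds.plots)
lqmm = fit_lqmm(ds.plots, tau=0.95, seed=0)
sfmm = fit_sfmm(ds.plots, seed=0)

lines = [
    line_from_upper_ci(lme, "S-P-LME"),
    line_from_upper_ci(lqmm, "S-P-LQMM"),
    line_from_frontier(sfmm, "S-P-SFMM"),
]
print(f"{'strategy':>10s} {'intercept':>10s} {'slope':>8s} {'SDImax@25.4cm':>14s}")
for line in lines:
    print(f"{line.strategy:>10s} {line.intercept:10.4f} {line.slope:8.4f} "
          f"{predict_nmax(line, 25.4):14.0f}")
# SDImax is the carrying capacity proxy: the stems/ha each frontier permits
# for a stand whose quadratic mean diameter is 25.4 cm.

tau, table = select_quantile(ds.plots, [0.90, 0.95], seed=0)
print(f"\nquantile with the smallest summed coefficient variance: {tau}")
print(table[["tau", "beta0", "beta1", "var_sum"]].to_string(index=False))
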