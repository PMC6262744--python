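"""Fit the three dynamic (remeasurement-based) strategies.

Dynamic plots record how density actually declined as mean tree size grew.
The density model fits the closed form of dN/ddg = -e^b0 dg^b1 N^b2 between
consecutive measurements; the mortality model treats deaths per period as
negative-binomial counts with a log link; the trajectory model predicts
stand diameter from density, anchored at each plot's first measurement.
"""

from selfthin import SimulationConfig, simulate_network
from selfthin.dynamic_models import (
    build_transitions,
    fit_density_model,
    fit_mortality_nbme,
    fit_trajectory_nlme,
)
from selfthin.thinning_capacity import line_from_ode_params, line_from_trajectory, predict_nmax

ds = simulate_network(SimulationConfig(seed=20181111))
dyn = ds.plots[ds.plots["is_dynamic"]]
transitions = build_transitions(dyn)
print(f"{len(transitions)} usable transitions from {dyn['plot_id'].nunique()} remeasured plots")

dens = fit_density_model(transitions, seed=0)
print("\ndensity model: beta =",
      tuple(round(float(b), 3) for b in (dens.beta0, dens.beta1, dens.beta2)),
      "| random effect on", "+".join(dens.random_effect_spec) or "none")
print(dens.comparison.to_string(index=False))

mort = fit_mortality_nbme(ds.deaths, seed=0)
print("\nmortality model: beta =",
      tuple(round(b, 3) for b in (mort.beta0, mort.beta1, mort.beta2)),
      f"| overdispersion theta = {mort.theta:.1f}")

traj = fit_trajectory_nlme(dyn, seed=0)
print("\ntrajectory model: alpha =",
      tuple(round(a, 3) for a in (traj.alpha0, traj.alpha1, traj.alpha2, traj.alpha3)))

for line in (line_from_ode_params(dens.beta0, dens.beta1, dens.beta2, "D-P-LME"),
             line_from_ode_params(mort.beta0, mort.beta1, mort.beta2, "D-P-NBME"),
             line_from_trajectory(traj)):
    print(f"{line.strategy}: line ({line.intercept:.3f}, {line.slope:.3f}) "
          f"-> SDImax {predict_nmax(line, 25.4):.0f} stems/ha")
# The density and mortality coefficients map to the self-thinning attractor
# through slope = (1+b1)/(1-b2); on short remeasurement series riding the
# frontier the individual coefficients are weakly identified but the line
# they imply is stable.
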