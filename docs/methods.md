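# Methods

`selfthin` estimates the self-thinning frontier — the upper boundary of the
size–density relationship ln N = b0 + b1 ln dg in even-aged, crowding-limited
forest stands — and the site carrying capacity it implies, by seven distinct
modelling strategies, and then compares what those strategies say about the
same data. Because long-term permanent-plot datasets of this kind are rarely
public, the package ships a synthetic plot network whose generative structure
matches the assumptions of every fitter, so each method can be validated by
parameter recovery rather than by eyeballing.

Notation: N is stand density (stems/ha), dg the quadratic mean diameter (cm),
G basal area (m²/ha), PBA the percentage of basal area held by the primary
(pioneer) genus, SDImax the maximum stand density index — the stems/ha the
frontier permits at a reference diameter dbase = 25.4 cm.

## The seven strategies

**Static, plot-level.** Single-occasion plot measurements carry frontier
information only through the upper edge of the point cloud.

1. *S-P-LME.* Gaussian linear mixed model
   ln N_ij = (b0 + u0i) + (b1 + u1i) ln dg_ij + e_ij with bivariate Gaussian
   plot effects (statsmodels `MixedLM`, ML so BICs are comparable across
   strategies). The frontier is the mean line with the intercept raised to
   the upper bound of its 95% confidence interval, b0 + 1.96·SE(b0). The
   1.96 multiplier is kept verbatim (an exact t quantile is available by
   option). When every plot has a single observation the random slope is
   unidentified; the fitter falls back to a random intercept (warning), and
   on degenerate zero-variance data to OLS.
2. *S-P-LQMM.* Linear quantile mixed model: the conditional tau-quantile
   (default tau = 0.95) of ln N given ln dg with a Gaussian plot random
   intercept. The likelihood kernel is the asymmetric Laplace density
   f(e) = tau(1−tau)/sigma · exp(−rho_tau(e)/sigma); its maximization is
   pinball-loss minimization, so with the random-intercept variance pinned
   at zero the fit is exactly classical quantile regression (tested against
   statsmodels `QuantReg`). The random intercept is integrated out by
   Gauss–Hermite quadrature (15 nodes by default; the integral is smooth
   and insensitive beyond ~10 nodes). `select_quantile` picks the tau in a
   candidate set minimizing the summed sampling variances of (b0, b1). The
   line again gets the upper-CI intercept shift.
3. *S-P-SFMM.* Stochastic frontier regression with composed error V − U,
   V ~ N(0, σv²) Gaussian noise and U ~ |N(0, σu²)| a half-normal one-sided
   shortfall from the frontier, plus a Gaussian plot random intercept
   ("true random-effects" frontier model). The marginal composed-error
   density is (2/σ)·φ(ε/σ)·Φ(−ελ/σ) with σ² = σu² + σv², λ = σu/σv. The
   random intercept is integrated by quadrature (default) or simulated ML
   over fixed standard-normal draws — both are provided because either is
   defensible and they agree on test data. The frontier line is Xβ itself:
   no CI shift, since U ≥ 0 already makes it a boundary. When σ̂u is pinned
   near zero the model warns that the frontier has collapsed onto OLS. On
   finite pure-Gaussian samples σ̂u is a boundary parameter with a
   half-spike-at-zero sampling distribution; the identified object is the
   conditional-mean line β0 − σu√(2/π), which is what the reduction tests
   assert.

**Static, tree-level.**

4. *S-T-LME.* Additive stand-density covariates from the tree list:
   x0 = Σ EF·(d/25.4)^1.6 / 100 and x1 = Σ EF·SG·(d/25.4)^1.6 / 100
   (EF the expansion factor, SG wood specific gravity, 25.4 cm the classical
   reference diameter, Reineke exponent 1.6). The scaling makes a uniform
   stand at d = 25.4 cm have x0 = N/100, so the unit-constraint fit
   a0·x0 + a1·x1 + e = 1 yields Nmax = 100/(a0 + a1·SGbar) exactly for
   uniform stands. The constraint is fitted at the 95th percentile with the
   same ALD machinery and a plot random intercept. One subtlety: with the
   unit response on the left, the 95th-percentile *density* frontier
   corresponds to the 0.05 quantile of the residual 1 − Xa (only 5% of
   stands may be denser than the frontier), so the kernel is evaluated at
   1 − tau internally. SGbar is basal-area weighted by default (arithmetic
   mean by option).

**Dynamic, plot-level.** Remeasured plots observe density decline directly.

5. *D-P-LME.* The mortality ODE dN/ddg = −e^b0 dg^b1 N^b2 has, for b2 ≠ 1,
   the closed-form solution
   ln N1 = (1/(1−b2)) ln[N0^(1−b2) + e^b0((1−b2)/(b1+1))(dg0^(b1+1) − dg1^(b1+1))],
   fitted between consecutive measurements as a nonlinear mixed model with
   Gaussian residuals. Candidate random-effect placements {b0}, {b1}, {b2},
   {b0,b1,b2} (independent effects, tensor-product quadrature) are fitted
   and compared by BIC. For b2 > 1 and b1 > −1 the ODE has an attractor
   line with slope (1+b1)/(1−b2) and intercept
   b0/(1−b2) + (ln(b2−1) − ln(b1+1))/(1−b2): that line is the strategy's
   self-thinning line. Parameter proposals that extinguish the trajectory
   are handled by a smooth floored-bracket surrogate with a hinge penalty,
   so the optimizer keeps a gradient in infeasible regions; the no-random-
   effect fit gets a Gauss–Newton polish that makes noise-free recovery
   exact to machine precision.
6. *D-P-NBME.* Deaths between occasions as negative-binomial counts,
   ln μ = b0 + u0i + b1 ln dg0 + b2 ln N0 + ln Δdg, the last term a fixed
   offset, Var = μ + μ²/θ. Counts are deaths per plot (density differences
   converted by plot area and rounded, logged per plot; NB needs integers).
   The random intercept is integrated by Gauss–Hermite quadrature; θ can be
   fixed, and with θ fixed very large the fit reproduces a Poisson GLM
   (tested). The NB mean is the Euler step of the same ODE, so the same
   attractor formulas give its line.
7. *D-P-NLME.* Trajectory model predicting size from density, anchored at
   each plot's first measurement (N1st, dg1st):
   ln dg = a0 + a1 ln N − [(a0·a2)²/(a0 + a1 ln N1st − ln dg1st)]·e^{−a3(ln N1st − ln N)}.
   The typeset source of this equation is ambiguous; the adopted grouping
   (squared numerator over the first-measurement gap) is isolated in one
   function (`trajectory_mean`) so an alternative reading is a one-line
   change. The anchor rows are conditioned on, not refitted as responses —
   including them would enter with structurally degenerate residuals and
   bias the error variance. The line is the reversed Reineke part solved
   for N: slope 1/a1, intercept −a0/a1.

## Comparison and carrying-capacity modelling

Each strategy's line is evaluated at dbase = 25.4 cm, SDImax =
exp(b0 + u_i + b1 ln dbase), with predicted plot random intercepts u_i where
the strategy has them (posterior means under the fitted model; strategies
without plot effects contribute a flat capacity profile). Strategies are
compared on plot-level SDImax with Scheffé's simultaneous contrasts
(critical value sqrt((k−1)·F(α; k−1, N−k)) times the pooled-ANOVA contrast
SE), summarized by an insert-and-absorb compact letter display. Scheffé is
already simultaneous, so no further multiplicity correction is applied.

Carrying capacity is then regressed on site covariates: the 19 bioclim
variables are screened one at a time by BIC, and the reported model uses
Shannon diversity, bio14 (precipitation of the driest month, mm) and a
quadratic in the pioneer basal-area share PBA, whose optimum −θ1/(2θ2) is
reported when the quadratic opens downward. Fit quality is reported as
relative RMSE, 100·RMSE/mean(SDImax).

## The synthetic plot network

Defaults (in `SimulationConfig`): 130 plots, one fifth dynamic with 3
occasions; generating frontier (12.15, −1.55); ODE parameters
(ln 1.55 − 12.15, 0.55, 2.0), chosen so the trajectory attractor coincides
with the static frontier; plot random-intercept sd 0.06, lognormal
observation noise sd 0.03 on N (both truncated at ±3 sd so frontier
containment is provable); NB dispersion θ = 30; static dg uniform on 14–46
cm; dynamic starts at dg 14–20 cm with 2–5 cm growth per period; plot areas
500–2,000 m² (static) and 0.5–1 ha (dynamic). These conditions put static
densities within 330–3,580 and dynamic within 670–4,680 stems/ha, the
envelope of the motivating network.

Static plots sit below the frontier by a truncated-exponential gap (scale
0.45, floor 0.08) — one-sided, which keeps the 0.95 quantile estimable —
further truncated so no plot falls below a 380 stems/ha sampling floor
(very sparse stands are not sampled as closed forest). Site covariates
shift the gap: wetter dry seasons (bio14) and higher Shannon diversity move
plots closer to the frontier, with effect sizes 0.08 and 0.05 log units per
sd. Dynamic plots start 0–0.45 log units below their own attractor
(approaching the frontier from below, which also gives the transient
curvature that makes the ODE parameters partially identifiable) and follow
the closed form with a plot effect on b0; recorded N adds the lognormal
noise. Death counts are drawn NB around the Euler-step mean — exactly the
mortality model's data-generating assumption. Tree lists use shifted
Weibull diameters (all above the 5 cm calliper limit) rescaled so the
recorded (N, dg) are reproduced exactly, with a Dirichlet species mixture
over three primary and two companion species with fixed wood specific
gravities.

What the generator does *not* emulate: measurement-interval heterogeneity
in time (growth is indexed by dg, not calendar years), ingrowth,
spatial structure or autocorrelation between neighbouring plots, species
composition change over occasions, and diameter-distribution dynamics
(each occasion's tree list is drawn fresh rather than grown). Passing
recovery tests therefore show the estimators are correct under their own
assumptions — not that those assumptions hold in any particular forest.

## Numerical choices

* One quasi-Newton (BFGS) core with up to 5 jittered restarts
  (scale-proportional jitter), Nelder–Mead polish for kinked ALD
  objectives, and Gauss–Newton polish for the nonlinear least-squares
  fits. Variance parameters are optimized on the log scale.
* Standard errors: BHHH (outer product of per-group score differences) for
  ALD-kernel fits — a numerical Hessian is unreliable across kinks — and
  the observed information (pseudo-inverse, since variance components may
  sit on a boundary) elsewhere. Plot-resampling bootstrap SEs are available
  by option for the LQMM.
* Infeasible-region handling in the nonlinear models is by smooth floored
  surrogates plus hinge penalties (constant penalties have zero gradient
  and trap line searches).
* NB linear predictors are clipped at ±700 before exponentiation so wild
  line-search proposals cannot overflow.
* All logs are natural; floats are serialized at 17 significant digits and
  parsed with correctly-rounded (`round_trip`) reading, so a fixed seed
  yields byte-identical output bundles.

## Validation design and problem sizes

The acceptance suite checks, at sizes chosen to keep the whole suite within
a few minutes: closed form vs adaptive ODE integration (20 random
admissible parameter sets, rel. err < 1e−6); attractor formulas vs
regressions on the far tail (dg up to 10³ cm — a mathematical limit, far
beyond biology) of long trajectories (< 1%); pinball and OLS oracle
equivalences; parameter recovery for all seven fitters (10–16 replicates at
120–1,000 observations each, mean estimate within 2 Monte-Carlo SEs of
truth); 0.95-quantile exceedance of 5% at n = 1,000; Scheffé familywise
error ≤ 5% over 10,000 null simulations; covariate-screening power and the
PBA-vertex recovery; byte-level determinism of the pipeline.

Recovery designs deserve one honest caveat: nonlinear mixed ML estimators
carry O(1/n) curvature bias, and marginalizing a random effect that enters
a strongly nonlinear mean (the ODE intercept, the NB linear predictor)
amplifies it. The recovery tests therefore use designs where that bias is
demonstrably below the Monte-Carlo resolution — modest random-effect
spreads for the density model, larger within-plot group sizes for the NB
model, anchored-covariate generation for the trajectory model. On designs
with large random-effect spread and short series the same fitters show
visible ridge bias in individual ODE coefficients even though the implied
self-thinning *line* stays accurate — which is also why the pipeline's
dynamic strategies report stable lines while their raw coefficients on
near-attractor data should not be over-interpreted.

## Known limitations

* The LQMM population line is the conditional quantile at u = 0; its
  marginal exceedance on heterogeneous plots is not exactly tau (the
  coverage test uses the pure quantile fit, and plot-conditional coverage
  is conservative under posterior shrinkage).
* On dynamic data riding the attractor, (b0, b1, b2) of the density and
  mortality models are identified mainly through the two line combinations;
  the third direction is a likelihood ridge. The package reports the line
  and flags the comparison table rather than pretending the coefficients
  are sharp.
* The tree-level strategy's plot capacities use the fitted constraint with
  posterior plot intercepts; where a0 + a1·SGbar ≤ 0 (outside the observed
  SG range) the plot is skipped rather than extrapolated.
* Scheffé assumes homoscedastic groups; strategy capacity spreads differ
  strongly in practice, making the test conservative for the tight groups.
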