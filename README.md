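# selfthin

Self-thinning frontiers and site carrying capacity in mixed forests, by
seven modelling strategies on one dataset.

In crowded even-aged stands, mortality is density-dependent: as the mean
tree grows, stem density N (stems/ha) is pushed down along an upper
boundary in (dg, N) space, classically the log-linear Reineke form

    ln N = b0 + b1 · ln dg,        b1 ≈ −1.6,

with dg the quadratic mean diameter (cm). The frontier evaluated at a
reference diameter (25.4 cm) gives the maximum stand density index
SDImax = exp(b0 + b1 ln 25.4) — a proxy for the site's carrying capacity.
Estimating that frontier is statistically awkward (it is a boundary, not a
mean), and ecologists have used very different strategies on very different
data. `selfthin` implements seven of them behind one API so their
disagreement can be measured:

| strategy | data | model |
|---|---|---|
| S-P-LME  | static plots | linear mixed model, upper-95%-CI intercept shift |
| S-P-LQMM | static plots | 0.95-quantile mixed regression (asymmetric-Laplace ML) |
| S-P-SFMM | static plots | stochastic frontier (half-normal one-sided error) with plot effects |
| S-T-LME  | tree lists | wood-density-aware additive SDI, unit constraint at the 95th percentile |
| D-P-LME  | remeasured plots | closed form of dN/ddg = −e^b0 dg^b1 N^b2, nonlinear mixed |
| D-P-NBME | remeasured plots | negative-binomial mortality counts, log link, Δdg offset |
| D-P-NLME | remeasured plots | size-from-density trajectory anchored at the first measurement |

Each fit is reduced to a `ThinningLine`, converted to plot-level SDImax,
compared across strategies with Scheffé's simultaneous contrasts (compact
letter display), and finally carrying capacity is regressed on site
covariates: Shannon diversity, dry-season precipitation (bio14) and a
quadratic in the pioneer species' basal-area share (PBA).

Because long-term permanent-plot networks of this kind are rarely deposited,
the package ships a first-class synthetic network generator
(`selfthin.synthetic_data`) whose generative assumptions match the fitters',
so every estimator is validated by parameter recovery. `docs/methods.md`
has the full model descriptions and numerical choices.

## Worked example

```
python examples/05_compare_and_capacity.py
```

prints (abridged):

```
self-thinning lines:
strategy  intercept  slope  sdi_max_at_dbase
 S-P-LME     11.205 -1.345           948.626
S-P-LQMM     12.427 -1.627          1290.591
S-P-SFMM     11.661 -1.503           898.125
 D-P-LME     12.493 -1.652          1272.936
D-P-NBME     14.956 -2.168          2821.473
D-P-NLME     16.559 -3.034           850.317

mean plot-level carrying capacity by strategy (shared letters = no significant difference, Scheffe 5%):
strategy  mean_sdi_max   n letters
D-P-NBME        2821.5  26       a
S-P-LQMM        1285.0 130       b
 D-P-LME        1272.9  26       b
 S-T-LME        1044.4 130       c
 S-P-LME         998.8 130       c
S-P-SFMM         914.7 130       d
D-P-NLME         850.3  26       d

carrying-capacity covariate model (relative RMSE 6.1% of mean SDImax):
     const:   1024.652 (se 134.965)
   shannon:      7.464 (se 57.687)
     bio14:      0.486 (se 0.308)
       pba:    625.458 (se 410.944)
      pba2:   -421.838 (se 294.217)
  optimum pioneer share: 74% of basal area
best single bioclim predictor: bio14
```

Reading this: the synthetic network was generated below the frontier
ln N = 12.15 − 1.55 ln dg, and the quantile strategy (S-P-LQMM) lands
closest to it — intercept 12.43 after the CI shift, slope −1.63,
SDImax ≈ 1291 stems/ha at 25.4 cm. The mortality-count strategy (D-P-NBME)
is the clear outlier (2,821 stems/ha, its own Scheffé letter): on short
remeasurement series that ride the frontier, ln dg0 and ln N0 are nearly
collinear and its coefficients are identified only along a ridge — exactly
the instability that makes strategy choice matter. The covariate model
recovers bio14 as the best single climate predictor and a downward-opening
PBA quadratic (the generator links capacity to bio14 and diversity; the
PBA curvature here is weak, with a wide CI on the optimum).

The other scripts in `examples/` walk through each capability: network
simulation, the three static fits plus quantile selection, the tree-level
density index, and the dynamic models.

A thin CLI wraps the same pipeline:

```
selfthin simulate --seed 7 --n-plots 50 --out data/
selfthin fit-static --plots data/plots.csv --strategy lqmm --tau 0.95
selfthin run-all --seed 7 --out results/
```

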