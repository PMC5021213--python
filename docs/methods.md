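# Methods

`fishclim` couples two predictive streams over one gridded climate:
an ensemble species-distribution model (SDM) of where a river fish's
climate is suitable, and climate-conditioned regressions of its von
Bertalanffy growth parameters. This note records the models, the numerical
choices, and what the synthetic study system does and does not emulate.

## The study design being modelled

The target design is a temperate (Britain-like) region on a regular
lon/lat grid, one species with presence/absence records per cell, six
bioclimatic predictors, a set of future climate projections (two climate
models × low/high emission pathways × two horizons, eight scenarios), and
a set of riverine populations with per-fish length-at-age data read from
scales. The analysis asks whether projected shifts in the species' climate
space are coupled with shifts toward smaller asymptotic size (L∞) and
faster growth (K) — the temperature–size rule pattern.

## Climate grid and variable reduction

A `ClimateGrid` holds one row per cell with six core variables (annual mean
temperature, mean diurnal range, isothermality = 100 × diurnal range /
annual range, mean temperatures of the wettest and driest quarters, annual
precipitation) plus auxiliary extremes (warmest-month maximum,
coldest-month minimum, annual range) needed to recompute isothermality
under perturbation. A warming scenario adds `delta_temp` to all
temperature-level variables, leaves the diurnal range alone (a uniform
shift cancels inside a within-day range), multiplies annual precipitation
by `precip_factor`, and recomputes isothermality from its definition, so
derived variables stay internally consistent.

Variable reduction is a greedy scan in a caller-supplied priority order:
keep a candidate only if its absolute Pearson correlation with every
already-kept variable is ≤ 0.70 (computed on the baseline grid only, since
selection precedes projection). The priority order is the tie-break — it
decides which member of a correlated pair survives; the default order is
the six core variables followed by the auxiliaries. Zero-variance
candidates are excluded with a warning because their correlation is
undefined.

## Growth core

Back-calculation uses the scale-proportional hypothesis. With the
species-level OLS fit S = u + v·L of scale radius at capture on capture
length, the length at the last annulus is

    L_a = −u/v + (L_c + u/v) · S_a / S_c .

A per-population regression is available behind a flag; the species-level
default reflects that scale–body allometry is a species property. Lengths
back-calculated to ≤ 0 (possible with a large positive intercept and a
small annulus radius) are dropped with a logged warning.

The growth model is the two-parameter von Bertalanffy function
L(t) = L∞(1 − e^(−Kt)), which pins L(0) = 0. Fitting is nonlinear least
squares (trust-region; `scipy.optimize.least_squares`) with positive
bounds, started from L∞₀ = 1.1 × max observed length and K₀ from
regressing −log(1 − L/L∞₀) on age through the origin; tolerances 1e-10,
at most 500 residual evaluations. A flat length profile is unidentifiable
and is returned flagged non-converged rather than raised, so one bad
population cannot stop a species. Each fish contributes one point: its
integer age at the last annulus and its back-calculated length there.

## Distribution–climate ensemble

Seven classifier families (GLM, GAM, MARS, classification tree, boosted
trees, random forest, neural network) are fitted to presence/absence
against the retained climate variables. The ensemble logic makes no
assumption about the roster size. Implementation notes:

* GLM is logistic regression with a very weak ridge (C = 10⁴) so separable
  niches do not diverge; GAM is logistic regression on a B-spline basis
  capped at 4 knots per variable (`SplineTransformer`, constant
  extrapolation); MARS is the package's own additive hinge regression (see
  below) on the 0/1 response with probabilities clipped to [0, 1]; the
  tree-based families and the neural network (one hidden layer of 8 units,
  standardised inputs) use scikit-learn defaults, each seeded from the run
  seed.
* Evaluation: 50 stratified 80:20 train/test repetitions shared across
  algorithms; each repetition is scored with the rank-based AUC (ties ½).
  Stratification guarantees two-class test folds whenever each class has
  ≥ 2 records; degenerate splits are redrawn a bounded number of times.
* Ensemble: members are the algorithms with mean AUC ≥ 0.7, weighted
  proportionally to their mean AUC (weights sum to 1); members are refit
  on all records, and the ensemble probability of a cell is the weighted
  mean of member probabilities. Evaluation AUCs are used only for
  selection and weighting.
* Two ensemble AUCs are reported and labelled: resubstitution (scored on
  the training records) and held-out (within-split member fits combined
  with the final weights and scored on each test fold, then averaged).
  The held-out number is the honest one; resubstitution is optimistic.
* Presence: cells with ensemble probability ≥ 0.6 (configurable; 0.5 and
  0.8 are reachable through the config).

## Growth–climate ensemble

Per-population L∞ and K are modelled separately against the same retained
climate variables with three families:

* **GLM** — Gaussian GLM fit by iteratively reweighted least squares
  (statsmodels).
* **GAM** — penalized B-spline additive model (statsmodels `GLMGam`),
  4 degrees of freedom per smooth, penalty weights chosen by the
  generalized cross-validation search of `select_penweight`. Two candidate
  smooth bases are tried — cubic (degree-3) and quadratic (degree-2)
  B-splines — and the basis with the lower leave-one-out score is kept.
  Spline predictors clamp new covariates to the training range, so
  projections beyond observed climate flatten instead of extrapolating
  wildly; this is the spline analogue of SDM "clamping" and means strong
  warming scenarios are increasingly carried by the GLM and MARS members.
* **MARS** — the package's own implementation: the forward pass adds
  reflected hinge pairs max(x−k, 0)/max(k−x, 0) while a step improves R²
  by ≥ 0.001; the backward pass prunes terms by cross-validated MSE with
  30 folds, capped at n (at the cap the score is the exact closed-form
  leave-one-out MSE of the linear-in-basis fit). Interactions between
  variables are not modelled; the fit is additive piecewise-linear and
  extrapolates linearly.

The skill score of every family, called GCV throughout, is operationalized
as the leave-one-out mean squared prediction error: the closed-form
hat-matrix identity for the GLM (a linear smoother), exact refits for the
others (GAM refits hold the penalty weights and basis degree fixed — the
standard "conditional on smoothing parameters" convention). Ensemble
weights are proportional to 1/GCV (lower GCV = better fit); a member with
GCV exactly zero takes all the weight, split equally among ties. Goodness
of fit is the RMSE between observed and ensemble-predicted values under
baseline climate.

Projection evaluates the ensembles at each population's cell under each
scenario grid. Scenario means carry the SE over populations and a
t-distribution 95% CI (the SE is across populations, not across ensemble
members); populations with a non-positive predicted parameter are excluded
from the means with a logged count.

## Range statistics and integration

The range centroid is the arithmetic mean (lon, lat) of presence cells —
the point about which the vector displacements of the cells sum to zero.
(A reading of "sum of the distances … zero" with scalar distances would
give the geometric median instead; the mean is the standard centroid and
was chosen deliberately.) Displacement between baseline and scenario
centroids is the haversine great-circle distance on a sphere of
R = 6371 km with the initial bearing, 0° = north, clockwise; no datum
transformation is applied, as sub-km datum effects are immaterial at 10-km
grid resolution. Coordinate shifts are tested with two-sample t-tests on
the latitudes and on the longitudes of presence cells, Welch
(unequal-variance) by default with the pooled Student's form behind a
flag, signed (original − projected) so a northward shift gives a negative
latitude t.

Coupling is a simple linear regression of the scenario-mean growth
parameter on the percent change in occupied cells (percent change, not raw
counts, is the predictor), with the F-test of zero slope; with eight
scenarios the degrees of freedom are (1, 6), and F = t² and
r² = F/(F + df₂) hold as identities. Per-scenario length-at-age curves
evaluate the growth function at integer ages for every population's
predicted (L∞, K); the mean curve is the per-age mean and the 95% band the
empirical 2.5th/97.5th percentiles across populations (distribution-free,
rather than a delta-method band on the parameters). Curves are built for
the baseline and the least- and most-warmed scenarios, spanning the
projection range.

## Synthetic study system

The generator produces the statistical structure the estimators assume,
not real geography:

* **Climate** — a regular grid over lon −6…2°, lat 50…59°. Annual mean
  temperature ≈ 9.5 °C declining 0.65 °C per degree north with a gentle
  eastward rise; continentality (annual range) grows eastward;
  precipitation is higher in the north and west. The warmest/coldest month
  extremes track annual mean temperature with |r| ≈ 0.9, giving the
  redundancy the 0.70-rule must remove, while the six core variables stay
  mutually below the threshold. Cell noise is independent Gaussian on top
  of smooth trends; no explicit spatial autocorrelation kernel is used —
  enough to exercise the estimators, not to mimic variograms of real
  climate surfaces.
* **Occurrences** — Bernoulli draws from a logistic niche on the climate
  variables. With a prevalence target set, a one-class draw re-centres the
  intercept (by bisection on the mean inverse-logit) and redraws a bounded
  number of times; without a target a saturated niche is returned as-is.
* **Growth** — per-population (L∞, K) are linear in the cell's annual mean
  temperature with Gaussian noise (defaults: L∞ = 420 − 12·T mm,
  K = 0.06 + 0.02·T yr⁻¹ — size falling and growth rising with warmth,
  with K > 0 across the grid's temperature range). Each fish gets an
  integer annulus age uniform on [1, max_age], is captured a uniform
  fraction of a year later, and carries a mean-one lognormal individual
  size factor that scales its whole trajectory. Scale radii follow
  S = 0.5 + 0.01·L with a Gaussian reading error shared between the
  capture and annulus radii of one fish (both are read off the same scale
  image), which keeps S_a ≤ S_c by construction and back-calculation
  unbiased; modelling the two reading errors independently would truncate
  at S_a = S_c and bias back-calculated lengths low for slow-growing old
  fish.

The default demonstration ("demo") system: 24 × 30 grid (720 cells), one
warm-adapted species (logit = −12 + 1.2·T, prevalence target 0.35), 40
populations of 50 fish with maximum age 10, eight warming scenarios from
+1.0 to +3.7 °C, seven SDM algorithms with 50 evaluation repetitions.
These sizes are chosen so a full run finishes in a few minutes on one core
while leaving all effects strongly identified; the whole run is
deterministic given the root seed, from which every stage derives its own
stream by stable hashing.

Passing tests on this system show the estimators recover structure they
are pointed at; they do not show anything about dispersal limitation,
river-network topology, biotic interactions, observation bias in atlas
data, or ageing error — none of which the generator emulates.

## Known limitations

* The GAM members flatten outside the training climate (clamping), so
  ensemble responses under extreme warming are conservative.
* The MARS implementation is additive (no hinge interactions).
* The SDM "GLM" uses a weak ridge for numerical stability on separable
  niches; coefficients are not exactly maximum likelihood there (the AUC
  ranking is unaffected).
* Percent change is reported rounded to two decimals, matching the usual
  presentation of such tables.
* No GeoTIFF/raster export; grids interchange as long-format CSV.
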