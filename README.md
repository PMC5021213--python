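# fishclim

Coupled climate-space and growth-shift modelling for river fishes.

Climate change moves species' ranges, but for ectotherms it also reshapes
their biology: warmer water tends to produce populations of smaller,
faster-growing individuals (the temperature–size rule). `fishclim` is a
pipeline for predicting both responses together for riverine fishes and
asking whether they are coupled. It is aimed at fish ecologists and
biogeographers who have gridded climate data, atlas-style
presence/absence records, and scale-read length-at-age data, and who want
ensemble projections of range and growth under warming scenarios — plus a
synthetic study system so every stage can be tested without any external
data.

## What it computes

**Distribution side.** Presence/absence on a climate grid is modelled
with seven classifier families (GLM, GAM, MARS, classification trees,
boosted trees, random forests, neural networks). Each is evaluated by 50
stratified 80:20 train/test repetitions scored with the rank-based AUC;
families with mean AUC ≥ 0.7 form a weighted-mean ensemble (weights ∝
AUC). Thresholding the ensemble probability at 0.6 gives the species'
*climate space* — the cells whose climate the ensemble deems suitable — a
potential, not realized, distribution. Range change per warming scenario
is summarised by occupied-cell counts and percent change, centroid
displacement (haversine distance, R = 6371 km, with bearing, 0° = north),
and Welch t-tests on the presence-cell latitudes and longitudes.

**Growth side.** Per-fish lengths at the last annulus are back-calculated
from scale radii by the scale-proportional method,
L_a = −u/v + (L_c + u/v)·S_a/S_c, with (u, v) from the species-level OLS
of scale radius on length. Each population's points are fitted with the
two-parameter von Bertalanffy growth function

    L(t) = L∞ (1 − e^{−K t})

giving its asymptotic length L∞ (mm) and growth coefficient K (yr⁻¹).
These are then regressed on the grid's climate with GLM, GAM and MARS,
combined by a weighted mean with weights ∝ 1/GCV (GCV = leave-one-out
mean squared prediction error), assessed by baseline RMSE, and projected
under each scenario's climate.

**Integration.** Scenario means of L∞ and K are regressed on percent
climate-space change (simple linear regression with an F-test; eight
scenarios give df (1, 6)), and per-scenario length-at-age curves with
empirical 95% bands are built from the per-population predictions.

Variable preparation reduces candidate climate variables by pairwise
Pearson correlation (|r| ≤ 0.70, greedy in a priority order), and the
synthetic-data module generates climate grids, logistic-niche occurrences
and temperature-size-rule growth data with all the structure above. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

The default demonstration runs the whole pipeline on the synthetic study
system: a 720-cell Britain-like grid, one warm-adapted species, 40
populations of 50 aged fish, and eight warming scenarios (+1.0 to
+3.7 °C). From a shell:

```sh
fishclim demo --seed 1 --outdir fishclim_demo
```

or from Python, `python examples/06_full_pipeline_demo.py`, which prints:

```
retained variables: ['annual_mean_temp', 'diurnal_range', 'isothermality',
                     'temp_wettest_quarter', 'temp_driest_quarter', 'annual_precip']
SDM members: {'GLM': 0.147, 'GAM': 0.147, 'MARS': 0.147, 'CTA': 0.122,
              'BRT': 0.145, 'RF': 0.145, 'ANN': 0.147}
ensemble AUC (held out): 0.907

        scenario  pct_change  distance_km  bearing_deg  mean_Linf_mm  mean_K_per_yr
 modelA_low_2050       42.45        70.59       352.17        298.59           0.27
modelA_high_2050       85.61       153.55       353.67        290.28           0.29
 modelA_low_2070       46.40        78.54       352.81        298.32           0.27
modelA_high_2070      129.14       236.98       355.43        284.53           0.31
 modelB_low_2050       51.80        91.17       355.46        296.41           0.28
modelB_high_2050      102.52       186.68       355.47        287.93           0.30
 modelB_low_2070       58.63       104.40       354.77        296.17           0.28
modelB_high_2070      150.00       276.78       355.06        281.26           0.32

coupling Linf_mm: slope = -0.1631 per % change, r2 = 0.992, F(1,6) = 716.5, p = 1.8e-07
coupling K_per_yr: slope = 0.0004098 per % change, r2 = 0.998, F(1,6) = 2535.5, p = 4.1e-09
```

Reading it: all six candidate climate variables survive the 0.70
correlation screen; all seven algorithms clear the AUC cutoff and share
ensemble weight in proportion to their skill. The species' climate space
expands in every scenario (+42% to +150%), more under stronger warming,
and the range centroid moves 71–277 km roughly north (bearings ≈
352–355°). Meanwhile the scenario-mean asymptotic length falls from
≈ 299 mm to ≈ 281 mm and the mean growth coefficient rises from 0.27 to
0.32 yr⁻¹ as warming strengthens, and the coupling regressions tie both
trends tightly to the percent change in climate space (negative slope for
L∞, positive for K, df (1, 6)) — the coupled range/growth shift the
pipeline exists to detect. The full artifact tree (CSV tables and JSON
manifests per stage) lands in `fishclim_demo/`.

The other scripts in `examples/` exercise one capability each: climate
generation and variable reduction, back-calculation and growth fitting,
the SDM ensemble, the growth-climate ensemble, and range-shift
statistics.

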