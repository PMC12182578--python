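# dasypop

Age-stratified dasymetric downscaling of census population counts to 100-m
grid cells, with random-forest weighting and exact mass conservation.

## The problem

Epidemiology, exposure assessment and planning need population denominators
on a fine, regular grid — including *who* lives in each cell, not just how
many people. Census counts, however, come per administrative unit
(township → county → city → province in the Chinese hierarchy), and units
vary wildly in size and contain large uninhabited areas. Dasymetric mapping
redistributes each source zone's count across its grid cells using
ancillary covariates that predict where people actually live.

`dasypop` implements the full production pipeline and its validation
battery:

1. **Inhabited mask** — a cell may receive population iff it has built-up
   area > 0 or building height > 0 and is not water.
2. **Density models** — for each population group *g* (total, 0–14, 15–59,
   60–64, ≥65), a random forest regresses township population density
   D(z,g) = P(z,g) / A(z) (persons/ha over the inhabited area A(z),
   untransformed) on eight covariate aggregates: built-up fraction,
   building height, nighttime lights, distance to road, POI density,
   elevation, slope, water. Townships are filtered to the middle 99% of the
   density distribution, split 85/15 into train/test, and the forest is
   tuned by exhaustive grid search over 13 tree counts ×
   9 depth caps (117 combinations) scored by 5-fold CV RMSE.
3. **Weighting and allocation** — the fitted model predicts a relative
   weight w(c) for every cell; each zone's count is allocated as

       pop(c) = P(z,g) · w(c) / Σ_{c′∈z} w(c′),   c ∈ z, inhabited,

   so that Σ_{c∈z} pop(c) = P(z,g) exactly (the pycnophylactic property).
   Cells of zones without census data become nodata.
4. **Age structure** — per-cell proportions of each age group against the
   summed-ages total; they sum to 1 wherever defined.
5. **Validation** — held-out R²/RMSE per group; per-city correlation and
   RMSE between the directly mapped total and the sum of the age-group
   maps; a rerun of the whole pipeline from county-level (coarser) data
   scored against the township census (R², RMSE, estimated-on-actual OLS
   slope), optionally stratified by city population size; and the
   within-unit standard deviation of per-cell age proportions, which
   separates genuinely age-stratified maps from products that multiply a
   constant regional age share into a total grid.

Because no gridded ground truth exists for real censuses, the package
ships a first-class synthetic-landscape generator (`synthetic_landscape`)
that builds seeded worlds — hierarchical zones, spatially autocorrelated
covariates with correlated urban cores, water, and per-age-group true
population surfaces that are known nonlinear functions of the covariates —
so every stage can be tested against exact aggregates of a known truth.

## Worked example

```python
import dasypop as dp

cfg = dp.RunConfig(
    landscape=dp.LandscapeConfig(n_rows=200, n_cols=200, n_cities=2,
                                 counties_per_city=3, townships_per_county=8,
                                 seed=7),
    outdir="example_out", split_seed=8, model_seed=9)
out = dp.run(cfg)
```

`out` now holds the five population GeoTIFFs (`population_total_pop.tif`,
`population_a0_14.tif`, …, plus `population_total_pop_sum.tif`, the sum of
the age-group maps), four proportion GeoTIFFs, the model report, the
consistency and validation reports, and a checksum manifest. Summarizing
the reports prints:

```
total    trees=1000 depth= 10 test_R2=0.98 test_RMSE=1.24 persons/ha
a0_14    trees=1000 depth= 10 test_R2=0.90 test_RMSE=0.30 persons/ha
a15_59   trees= 800 depth= 10 test_R2=0.99 test_RMSE=0.78 persons/ha
a60_64   trees=  80 depth= 10 test_R2=0.95 test_RMSE=0.10 persons/ha
a65plus  trees=  80 depth= 10 test_R2=0.96 test_RMSE=0.13 persons/ha
consistency: mean r = 1.000, mean RMSE = 0.25 persons/ha
county-source validation (vs township census):
            r2      rmse  slope
total    0.980  1287.858  0.925
a0_14    0.975   155.746  0.914
a15_59   0.963  1350.929  0.900
a60_64   0.983    57.226  0.952
a65plus  0.981    95.838  0.953
```

Reading the output: each row is one tuned forest with its winning
hyperparameters and held-out accuracy on township densities; the
consistency line says the independently mapped total and the sum of the
four age maps agree almost perfectly per city; the county-source table
shows that mapping from the coarser county counts and re-aggregating to
townships still recovers the township census well, with OLS slopes below 1
(mild underestimation in the most populous townships) — and by mass
conservation the township-source product is exact at township level, so
these numbers are a lower bound on its accuracy.

The same workflow is available from the shell:

```sh
dasypop run --seed 7 --outdir example_out
dasypop simulate --seed 7 --outdir world/     # landscape + census only
dasypop fit --seed 7 --outdir fit_out         # models + report only
```

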