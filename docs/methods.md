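# Methods

## Model and procedure

`dasypop` performs areal disaggregation with a covariate-driven weighting
layer. The source zones are the finest administrative units with census
counts (townships); the target zones are 100-m grid cells, so cell values
in persons per cell are numerically persons per hectare.

**Inhabited mask.** A cell is eligible for population iff
`builtup_frac > 0 or building_height > 0` and `water == 0`. The
inequalities are strict with no epsilon. All densities, weights and
allocations are gated by this mask; estimates outside it are exactly zero.
A zone whose inhabited area is zero but whose census count is positive is
recorded in `uninhabited_zones.csv` as a stranded count — a conservation
violation surfaced to the caller, never silently dropped or redistributed.

**Training table.** One row per township with positive inhabited area.
Covariate aggregates are the *mean over inhabited cells* of each of the
eight layers — chosen to match the inhabited-area denominator of the
density target; an all-cell mean is available via `aggregate_covariates(
mask=None)`. The target is density in persons/ha, deliberately
untransformed: a log transform would compress errors in the densest
townships, which are exactly where goodness-of-fit matters.

**Middle-99% filter.** Before splitting, townships outside the middle 99%
of the group's density distribution are dropped: strict exclusion outside
the 0.5th–99.5th linearly interpolated percentiles, applied per group on
that group's own density (models are trained separately, so each group
defines its own tails). Below 200 rows the tail percentiles are dominated
by a handful of observations, so the filter is skipped with a warning.

**Split and tuning.** A seeded shuffle puts ⌊0.85·n⌋ rows in training and
the rest in test; the split is shared across groups so all five models see
the same geography. Tuning is an exhaustive grid over forest sizes
{5, 10, 20, 40, 60, 80, 100, 150, 200, 400, 600, 800, 1000} and depth caps
{10, 20, 40, 50, 60, 70, 80, 90, 100} — 117 combinations — scored by the
pooled out-of-fold RMSE of a seeded 5-fold split (folds shared by all
combinations). The minimum wins; ties break toward fewer trees, then a
shallower cap, so the selected model is the cheapest of the equally good.
The winner is refit on the full training split.

*Implementation note.* The grid is scored exactly but without 585 separate
forest fits: the first k trees of a seeded scikit-learn forest are
identical to a fresh k-tree forest with the same seed, so one max-size fit
per (depth, fold) scores all 13 tree counts via prefix averages of the
per-tree predictions; and once no tree reaches its depth cap, all deeper
caps provably yield the same forest and inherit its scores. A test
verifies equality with naive per-combination refits.

**Allocation.** Per zone, `pop(c) = P_z · w(c) / Σw` over inhabited cells,
computed in double precision with a final rescale and a largest-weight
residual correction, so the per-zone sum matches the census count to the
last representable bit (measured worst relative error ≈ 3·10⁻¹⁵). If a
zone's weights are all zero the count is spread uniformly over its
inhabited cells (logged); with no inhabited cells it is reported
unallocatable. Outputs are continuous densities — no integer rounding.
Zones missing from the census table get the nodata sentinel (−9999) in
every product.

**Age structure.** The total map and the four age-group maps are produced
by independent model/weighting/allocation passes. Proportions divide each
age map by the *sum* of the four age maps (not the directly mapped total),
so they sum to 1 wherever defined; cells with zero summed population or no
census data are nodata. The agreement between the two totals is summarized
per city by Pearson r and RMSE over cells where both are valid and at
least one is nonzero; cities where either map is constant get a null r.
Summaries report the mean and the 25th–75th-percentile IQR across cities.

**Validations.**
- *Held-out fit*: R² and RMSE of each model on the 15% test townships.
- *Coarse-source rerun*: the identical pipeline trained and allocated from
  county-level data, summed back to townships and compared with the
  township census: R², RMSE in persons, and the OLS fit of estimated on
  actual — this direction makes "slope < 1" literally mean underestimation
  in populous townships. Optionally stratified by the standard city-size
  classes (<0.5 M, 0.5–1 M, 1–5 M, 5–10 M, >10 M inhabitants; intervals
  closed on the left, so a city of exactly 1.0 M is "large").
- *Spatial variation*: per-unit SD (population convention, ddof=0,
  configurable) of cell proportions at any admin level, with mean and IQR
  across units. The comparison baseline multiplies the total map by
  constant county age shares, reproducing the behaviour of products whose
  grids within a county share one proportion; its county-extent SD is 0 by
  construction.

## Synthetic landscapes

The generator builds the statistical situation the pipeline assumes, not
any real geography. Defaults (chosen once as a desk-scale analogue of a
provincial study area):

| parameter | default | rationale |
|---|---|---|
| grid | 400×400 cells at 100 m | 40 km × 40 km; allocation and validation complete in ~2 min on one CPU |
| hierarchy | 4 cities × 5 counties × 10 townships | 200 townships ≈ 160-row training tables; enough for stable tuning |
| covariate correlation length | 12 cells | kilometre-scale autocorrelation of land-cover fields |
| urban cores | 4, decay 40 cells | each city anchored by a core that jointly raises built-up, height, lights and POIs — the covariate collinearity real cities show |
| water fraction | 0.08 | typical open-water share of a lowland province |
| density scale | 60 persons/ha at a fully urban cell | ~6000 persons/km² urban-core density |
| density noise sd | 15% of the signal sd | measurement/idiosyncratic variation that still leaves the covariates predictive |

True total density is a monotone nonlinear function of the covariates —
increasing in built-up fraction (power 1.3) and building height
(saturating), decreasing exponentially in slope and distance to road —
plus Gaussian noise, truncated at zero, and exactly zero outside the
inhabited definition. Age shares are a softmax of per-group logistic
trends in space and in an urbanity proxy (the standardized built-up
fraction): working-age share rises with urbanity, child and elderly shares
fall, and mild east–west/north–south gradients create the cross-township
age-structure variation the variation metric is designed to detect. The
four group surfaces sum to the total surface *exactly* (the total is
defined as their sum), and census tables at any level are exact cell sums
of the truth, so conservation checks have a bit-level reference.

What the generator does **not** emulate: real administrative geometry
(zones are rectangular tessellations), within-township census error,
temporally mismatched covariates, and the heavy right tail of national
density distributions (the middle-99% filter therefore usually engages
only on tables with ≥200 rows). Passing tests demonstrate the machinery —
conservation, masking, protocol fidelity, recoverability of a known
density function — not the accuracy of any real-world product.

## Numerical choices

- Zone membership is by cell-center containment; a center on a shared
  boundary goes to the polygon earliest in input order (deterministic).
  Same-level overlaps are an error naming the offending ids.
- Zonal aggregates over empty zones are NaN, never 0; downstream stages
  decide explicitly.
- Within-unit SD uses a two-pass (mean-then-deviations) computation:
  the one-pass formula loses all significance on near-constant proportion
  fields.
- Percentiles (middle-99% filter, PDP sweep ranges, IQRs) use linear
  interpolation.
- Grid I/O writes GeoTIFF tags (ModelPixelScale, ModelTiepoint,
  GDAL_NODATA) via tifffile; round-trips are bit-exact for integer and
  float grids. Coordinates are planar meters in synthetic worlds; real
  rasters pass their transform through unchanged — no reprojection is
  performed.

## Known limitations

- Hierarchies are strict trees; directly administered units that skip a
  level must be given synthetic intermediate parents.
- The allocator streams zone by zone in one process; national-scale
  rasters would need tiling, which is out of scope.
- Tuning assumes the candidate lists fit in memory as a dense CV table;
  that is intentional — the table is part of the model report.
- The uniform fallback for zero-weight zones is a pragmatic choice; any
  within-zone structure in such zones is unknowable to the model.
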