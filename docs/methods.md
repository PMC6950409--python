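# Methods

## The model

lurkit estimates monthly PM2.5 at station-month resolution with an
ordinary-least-squares linear model

    Y = β0 + Σ βi·Xi + ε,

where Y is the monthly mean concentration (µg/m³) and the Xi are
GIS-derived candidate predictors.  Predictors fall into six classes:

* **land_use** — summed area of a land-use class within a circular
  buffer (hectares by default; m² or in-buffer fraction configurable);
* **ndvi** — buffer-mean vegetation index in [−1, 1], monthly when a
  16-day composite stack is available, static otherwise;
* **distance** — Euclidean distance (m) to the nearest point/line
  feature of a layer (roads, railways, airports, quarries);
* **meteorology** — monthly station means interpolated to monitor
  coordinates by inverse distance weighting;
* **copollutant** — co-located gas/particle measurements when the
  network provides them (e.g. PM10, NO2, SO2); absent otherwise;
* **season** — 0/1 dummies from a named month-partition scheme
  (default: meteorological spring Mar–May, fall Sep–Nov; the scheme is
  an explicit assumption and fully configurable).

Buffer features use circular focal statistics on a planar grid of 50 m
square cells: a cell belongs to the kernel iff its center lies within
the radius of the focal cell's center (standard GIS circle semantics —
the rule is stated because tools usually aren't explicit about it).  At
grid edges the statistic uses in-grid cells only; no padding.  The
default radius ladder is 250, 500, 750, 1000, 1250, 1500, 1750, 2000,
2500, 3000, 4000, 4250, 4750 and 5000 m.

## Supervised stepwise selection

Each candidate carries a direction prior (+1/−1/0).  Defaults: positive
for built/transport/industrial/quarry classes, co-pollutants,
temperature and spring; negative for NDVI, relative humidity, rainfall,
UV, fall and airport nearest-distance; unconstrained otherwise.  All
priors are overridable.

1. **Screen**: candidates whose Spearman rank correlation with the
   response contradicts a nonzero prior are dropped; zero-variance
   columns are dropped with a log entry.
2. **Rank**: survivors are ordered by univariate R² (ties broken by
   name, as are all ties in the procedure).
3. **Forward step**: candidates are re-ranked by the R² of the
   tentatively extended model; the best candidate passing all three
   gates is added — coefficient p-value < `p_enter` (0.1), every VIF in
   the tentative model < `vif_max` (3), no nonzero-prior coefficient
   sign flip.  Gate failures are logged as skips and the next candidate
   is tried.
4. **Backward step**: after each accepted add, terms whose p-value has
   risen to ≥ `p_enter` are removed, least significant first.
5. The loop ends when no candidate is addable; the final term set is
   re-fitted and every gate re-verified.  If nothing survives, an
   intercept-only model is returned with a warning.

Conventions: VIF_j = 1/(1−R²_j) from regressing predictor j on the
other terms (with intercept); a single-term model reports VIF = 1;
perfect collinearity reports ∞ and fails the gate.  Partial R² is the
squared partial correlation, computed as t²/(t²+df_resid) — equal to
residual-on-residual squared correlation (verified in tests).  RMSE is
the root mean squared residual.  The same data may surface two
different "ρ"-like quantities in this literature — the Spearman
pre-screen statistic and the coefficient p-value threshold — so the
code names them `spearman rho` and `p_value` and never overloads one
symbol.

No same-layer exclusion rule is imposed across buffer radii: the VIF
gate alone arbitrates, so a layer may legitimately enter at more than
one radius.

The whole selection is deterministic given the design matrix and
configuration; every add/skip/remove decision is logged to a
`SelectionTrace` (JSON-lines exportable).

## Validation and mapping

10-fold cross-validation assigns station-month rows to seeded random
folds (sizes differ by ≤ 1; a leave-station-out mode exists but is not
the default, since sparse networks — two monitors in one of the target
settings — cannot support station-level stratification).  By default
folds re-fit the coefficients of the already-selected terms; a
`refit_selection` mode re-runs the entire selection per fold for
honesty analyses.  The headline metric is the pooled out-of-fold R²
and RMSE over concatenated predictions; per-fold values are also
reported.

Prediction surfaces evaluate the fitted equation cellwise on predictor
rasters (static layers broadcast across periods).  Negative cells are
floored at zero only in exported maps — never in CV metrics — with the
floored-cell count recorded.  Period averages are cellwise arithmetic
means; exceedance summaries count cells strictly above named
thresholds (defaults: WHO annual 10 and 24-h 25 µg/m³; Indonesian
national annual 15 and 24-h 65 µg/m³).

## The synthetic-study generator

`simulate_study` emulates the data a desk-scale LUR study consumes:

* **Grid**: 200 × 200 cells of 50 m (10 × 10 km).
* **Land use**: quantile-thresholded smoothed Gaussian fields (sigma
  500 m) give spatially contiguous classes at target area fractions
  (defaults: Residential 0.08, Commercial 0.15, Industrial 0.10,
  Forest 0.35, remainder unclassified — chosen so the residential
  buffer-area marginal at 4250 m lands in the few-hundred-hectare range
  typical of published descriptive tables).  Roads/railways are random
  straight transects clipped to the grid; airports/quarries are random
  points.
* **NDVI**: a static smooth base field (mean 0.25, sd 0.08) plus a
  seasonal cosine (amplitude 0.05, wet-season peak) and monthly
  regional anomalies, both modulated by local greenness — barely
  vegetated cells barely cycle, a basic property of real phenology
  without which all buffer radii would share one temporal signal —
  generated at the 16-day compositing cadence and composed monthly by
  maximum (the satellite maximum-value-composite convention; mean is
  configurable).
* **Meteorology**: five stations; each variable is a fixed spatial
  gradient + seasonal cosine + shared monthly anomaly + daily noise,
  clipped to physical bounds.  The monthly anomalies matter: pure
  sinusoidal seasonality would make any three seasonal predictors
  exactly collinear (they span sin/cos), which no real climate does.
  Monthly station means are IDW-interpolated (power 2, all stations,
  1 m snap tolerance) to monitor coordinates; aggregation happens
  before interpolation.
* **Response**: 17 monitors, 36 months (2016–2018) by default.  The
  ground truth is a four-term model — temperature +5.797,
  NDVI_1500m −77.419, relative_humidity −0.779,
  Residential_4250m +0.039 (µg/m³ per unit) — with intercept −60.566,
  i.e. the coefficient pattern of a published tropical-megacity LUR,
  plus Gaussian noise.  By default the noise SD is calibrated so the
  generating model explains R² = 0.8 of the response variance; PM2.5 is
  truncated at 0 and the exact noiseless linear predictor is returned
  alongside so tests need not fight truncation.
* **Candidates**: 40 by default — 4 classes × 6 radii (250, 500, 1000,
  1500, 2500, 4250 m), NDVI × 6 radii, 3 nearest-distance layers, 5
  meteorological variables, 2 season dummies.

All generators draw from `numpy.random.default_rng`; a study seed is
split with `SeedSequence` so identical seeds give bit-identical output.

### What passing tests do and do not show

The generator reproduces the statistical structure the method assumes —
spatial contiguity, seasonal cycles, buffer-nested collinearity, a
linear truth — but not real-data pathologies: no cloud/QA gaps in NDVI,
no missing monitor days, no instrument drift or calibration offsets, no
spatially correlated model error, and planar geometry with no CRS
issues.  Passing recovery tests therefore demonstrates that the
selection machinery is correct and well-behaved under its own
assumptions, not that any particular real-world model is right.

One consequence of nested buffers deserves emphasis: radii of the same
layer are strongly correlated, so the *exact* radius of a buffered
truth variable is only weakly identified — published models themselves
retain single layers at several radii with low VIFs.  Recovery is
therefore scored at the layer level (the same layer selected at any
ladder radius counts), while coefficient-error summaries use only
exactly matched terms, whose scales are comparable to the truth.
Measured over 50 seeds at the default conditions, all four true
predictors are recovered (layer level) in ~96% of runs with a mean
absolute relative coefficient error of ~8%; the stricter
adjacent-radius-only reading yields ~82%.

## Numerical choices

* Focal statistics accumulate kernel offsets in row-major order — the
  same order a per-cell loop uses — and the exactness tests use
  integer-valued rasters so float summation order cannot blur the
  comparison; membership is decided on exact integer offset distances.
* Cell lookup uses half-open intervals [edge, next edge): a point on a
  shared edge belongs to the upper/right cell; row 0 is the southern
  row.
* Monthly aggregation requires ≥ 75% of calendar days present
  (configurable); months below the threshold are dropped.
* IDW returns a station's value exactly within a 1 m snap tolerance
  (avoiding division by zero) and is exact at stations, bounded by the
  observed value range, and continuous elsewhere.
* Rank deficiency raises an error naming the collinear columns rather
  than silently dropping them.
* Problem sizes in the repeated-run evaluations (50 seeds × 510
  station-months × 40 candidates; 60 × 60 oracle rasters) were chosen
  as the smallest sizes at which the asymptotic behavior of the gates
  and recovery is stable.

## Known limitations

* No kriging, no regularised or spatial regression, no AIC/BIC modes —
  the stepwise procedure is the method under study.
* No CRS reprojection; coordinates are planar meters.
* Wind direction is generated and passed through but never
  vector-decomposed into candidate columns.
* The land-use buffer unit (hectares) is a convention, not a standard;
  fraction and m² are provided for sensitivity checks.
* Cross-city transfer, health-impact estimation and cartographic
  styling are out of scope.
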