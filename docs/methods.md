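# Methods

## Model

The package estimates a dasymetric weighting surface by random-forest
regression of log population density on zonally-aggregated covariates,
then redistributes census counts over it.

**Response.**  For census unit *u*: d_u = count_u / area_u in people/km²
(areas from the projected unit geometry; any fixed area unit only shifts
the log response by a constant, km² is used and stated in exports).  The
response is ln d_u.  Zero-count units are removed before fitting — the
log is undefined there — but still receive predicted weights and counts
at redistribution time.  `log10` and `sqrt` transforms exist behind a
config switch for comparison runs; the natural log is the default because
it best evens out the heavy right tail of density.

**Forest.**  500 regression trees (a stable OOB error plateau; the value
is a parameter).  Each tree is fit on a bootstrap sample of size N; splits
choose the best of `mtry` randomly drawn covariates; trees grow until
terminal nodes hold at most round(N/1000) observations — a single
observation when N < 1000 — using round-half-to-even (config-overridable).
Individual CART trees come from scikit-learn
(`DecisionTreeRegressor(max_features=mtry, min_samples_split=node_cap+1)`);
bootstrap, OOB accounting, importance, tuning and elimination are
implemented in `density_forest`.

**mtry tuning.**  Stepwise OOB-MSE minimisation starting at
max(1, ⌊p/3⌋), multiplying/dividing by a step factor of 2, accepting a
step while the relative improvement is ≥ 0.05, searching both directions;
the accepted candidate with the lowest OOB MSE wins (ties to the smaller
value).  Tuning forests use the full 500 trees by default: with very few
training units a 50-tree tuning ensemble makes the OOB objective too
noisy to step on reliably; the 50-tree shortcut remains available via
`tune_n_trees`.

**Covariate elimination.**  Iteratively: tune mtry → grow forest →
compute OOB permutation importance (per tree, the increase in OOB MSE
after permuting one covariate among that tree's OOB rows, averaged over
trees; node-purity importance — mean total decrease in residual sum of
squares — is reported alongside) → drop every covariate whose importance
is "zero".  *Zero* is operationalised as: non-positive, **or** no larger
than 2% of the top score.  Rationale: fully grown regression trees fit
residual noise with whatever covariates are available, which gives even
pure-noise covariates a small but genuinely positive permutation
importance (the reference R implementation reproduces this: noise columns
score +0.002–0.007 against a signal at 0.57, with z-scores up to ~6), so
a sign or significance rule never removes them; 2% of the maximum is
"zero at the resolution of an importance plot" and removes exactly the
covariates with no visible predictive capacity.  The loop terminates when
all scores clear the bound or one covariate remains; an iteration that
would drop everything keeps the best-ranked covariate.

**Prediction.**  Per pixel, w = exp(mean over trees of the predicted log
density), accumulated in float64, stored float32, computed in row tiles
whose results are independent of tile size.  No smearing or bias
correction is applied to the back-transform: the plain back-transformed
mean is the summary that validates best for this model class.  Tree means
cannot leave the training response range; predictions are clipped to that
range so the no-extrapolation property holds exactly rather than to float
rounding.  Water (class 210) and missing (class 230) land-cover pixels
are forced to zero weight after prediction; because redistribution
normalises weights within each unit, applying zeros before or after
normalisation is equivalent.

**Redistribution.**  Pixel p in unit u gets count_u · w_p / Σ_{q∈u} w_q —
conservation per unit is exact by construction.  A unit whose weights sum
to zero but whose count is positive falls back to a uniform within-unit
split (conservation must hold regardless of the weight surface).
Scaling to an external national total multiplies every pixel by
target/current.  Projection applies P_d · e^{rt} pixelwise, with the
urban or rural rate chosen by an urban-extent mask; the default released
order is project-then-adjust, both orders are supported and commute when
r = 0.  People-per-hectare divides by the pixel area in hectares (at the
nominal 100 m resolution, 1 pixel = 1 ha exactly).

## Raster conventions

Pixel-centre semantics throughout: a pixel belongs to the polygon
containing its centre (no all-touched rasterization), so unit rasters are
true partitions — which redistribution requires; distances are measured
between pixel centres.  All layers share one grid template bit-exactly.
Distance and buffering work requires a projected metric CRS; synthetic
landscapes use a planar metric frame directly.  Majority-aggregation ties
break to the smallest class code.  Equidistant ties in the distance
transform and nearest-neighbour fill follow the deterministic internal
choice of `scipy.ndimage.distance_transform_edt`; outputs are fully
reproducible, and tests assert distance-minimality of the chosen source
cell rather than a particular tie winner.  Empty feature classes are
dropped from the stack (logged) instead of being encoded as infinite
distance, keeping the training matrix finite.  Census boundaries are
buffered 10 km by default before gridding so distance covariates are
stable near borders; the buffered region is predicted but the surface is
cropped to census boundaries before redistribution.

## One-level-up validation

Counts are aggregated to the next admin level up for estimation *and*
redistribution; pixel sums inside the original fine units are scored
against the withheld fine counts with RMSE, %RMSE = 100·RMSE/mean(count)
(mean over all fine units, including zero-count ones) and MAE.  Percent
residuals 100·(o−p)/o are bounded above by 100 and undefined at o = 0
(such units are excluded from residual maps but retained in RMSE/MAE).
Baselines reuse the same redistribution machinery with constant weights
(areal, GPW-like) or a two-level urban/rural weighting (GRUMP-like,
default ratio 5:1 — a plausible urban-rural density contrast).  The
total-country variant pools all units into one national count before
redistribution, eliminating the census anchor and measuring the weight
surface alone.

## Synthetic landscapes

`synthetic_landscape` emulates the data structure the model assumes, with
ground truth for recovery tests:

* **Truth density.**  λ(p) = β₀ + β₁·exp(−d_built(p)/d_scale) +
  β₂·1[built](p) + β₃·field(p) + ε, ε ~ N(0, σ²) white per pixel (a
  correlated option exists but defaults off); water and missing pixels
  have density 0.  d_built is the distance to the nearest built-up pixel:
  density is plateau-like across the built fabric and decays outward —
  the classic urban density profile, and the reason distance-to-built is
  the dominant covariate in real fits.  Defaults: β₀ = ln 50 (a 50
  people/km² rural baseline), β₁ = 2.5, β₂ = 2.0 (together ≈ 90× denser
  in built cores, a realistic urban:rural contrast), β₃ = 0.5,
  d_scale = 2 km, σ = 0.2.
* **Settlements.**  Eight points whose built-up radii follow the rank-size
  rule r_k = 2500 m · k^(−1/2) (Zipf populations at constant density),
  floored at 400 m; patches with radius ≥ 1 km form the urban extent.
  This yields one primate city, several towns and villages — and hence a
  continuum of unit-level densities, which real settlement systems have.
* **Admin units.**  A nested Voronoi tessellation whose seeds are sampled
  with probability ∝ population^0.5.  Census geographies are loosely
  population-balanced — dense metros split into many small units, sparse
  countryside into large ones — and this is essential here: the forest
  cannot predict outside the range of *unit-level* training densities, so
  units must span the pixel-level density range, as they do in real
  census data.  The 0.5 exponent keeps a realistic spread of unit counts
  (exact balance would make every count identical).  Fine cells are
  pixel-wise Voronoi regions of the fine seeds; coarse units group whole
  fine cells by nearest coarse seed, so nesting is exact.
* **Counts.**  Zonal sums of exp(λ)·pixel-area, rounded; the per-coarse
  rounding residual is assigned to the largest fine member so fine counts
  nest exactly in coarse counts.
* Regeneration from the same (spec, seed) is bit-identical.

What passing tests on these landscapes do *not* show: robustness to
geodesic distortion (the frame is planar), census geocoding errors,
misaligned or temporally inconsistent covariates, or spatially correlated
enumeration error — all present in real inputs.

## Study sizes used in tests

The cross-scale baseline comparison runs on a 200×200 grid with 12
coarse / 120 fine units (σ = 0.2), ten seeds.  With only 12 training
units, bootstrap averaging visibly shrinks predictions toward the mean
density — the "degrade gracefully toward mean prediction" regime of
coarse census inputs — which is why the ordering against baselines is
the tested property there, not unbiasedness.  The pooled total-country
test runs at 150 coarse / 600 fine units, the training scale at which
the method's near-1:1 observed-vs-predicted behaviour emerges (real
applications train on hundreds to thousands of units); there the
total-country slope criterion [0.9, 1.1] is met alongside the
anchored-vs-pooled RMSE ordering.  The attenuation at N = 12 is a
property of the method, not this implementation: the reference R forest
on the identical 12-row training table attenuates at least as strongly.

## Numerical notes

* One RNG stream per run; bootstrap draws, tree seeds and permutation
  seeds derive from it reproducibly.  Same (seed, table) → bit-identical
  forests, rasters and reports.
* Conservation assertions use 1e-6 relative tolerance; observed errors
  are at the 1e-14 level (float64 bincount sums).
* Zonal statistics exclude nodata pixels; a unit with zero pixels is
  dropped from the training table with a warning; a unit smaller than a
  pixel that captures no centre is logged.
* Model bundles serialise via joblib with a format version; the metadata
  report (JSON) carries parameters, OOB statistics and the importance
  ranking, so each mapping run self-documents.

## Known limitations

* ESRI ASCII grids and GeoJSON are the only on-disk geo formats; there is
  no GeoTIFF/Shapefile reader, and no reprojection — inputs must already
  share a projected CRS.
* Per-pixel uncertainty (tree variance) is not emitted.
* The two-stage zero/non-zero density model that would allow predicted
  zeros outside water/missing classes is out of scope; back-transformed
  log predictions are strictly positive elsewhere.
* Areas on geographic (degree) grids are not computed; metric CRS only.
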