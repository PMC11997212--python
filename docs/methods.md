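# Methods

This note records the models implemented in `birdscape`, the numerical
conventions adopted where a published workflow leaves details open, what
the synthetic-data generator does and does not emulate, and the package's
known limitations.

## Acoustic diversity metrics

Detections arrive as rows of (site, start time in seconds from recording
start, end time, species, confidence in [0, 1]). The cleaning pipeline has
a fixed order — confidence filter, then per-site singleton removal, then
rare-species review — because the stages interact: a two-detection pair
whose second member fails the confidence filter becomes a singleton only
after filtering. The order is regression-tested.

* **Confidence filter**: inclusive threshold, `confidence ≥ 0.8` by
  default ("minimum confidence" reads as ≥).
* **Singletons** are judged per species × site: one detection of a species
  at a site is treated as incidental and dropped there, even if the
  species is well supported elsewhere.
* **Rare-species review**: species with ≤ 10 detections overall are
  flagged for manual audit. The audit itself is outside the software; the
  caller passes back the list of confirmed misidentifications, and the
  function refuses to delete anything that was not flagged.

**Vocal activity rate.** Recording time is partitioned into consecutive
900 s bins anchored at each site's own recording start (recorder-anchored
rather than wall-clock quarter hours, so VAR is invariant to the minute of
deployment). A detection occupies the bin containing its start time;
detections spanning a bin boundary are not split (classifier windows are
~3 s, so spans are negligible). VAR = distinct occupied bins / days
recorded, where days recorded is the actual fractional recorded duration,
not calendar days. VAR is bounded by 96·(elapsed days)/(days recorded).

**Site metrics.** Richness counts species with VAR > 0; total VAR sums
them; Shannon diversity uses VAR shares in place of abundances (natural
log). A site left with no species reports richness 0, VAR 0 and Shannon 0
with a warning — entropy is undefined there, and 0 keeps downstream tables
rectangular.

## Raster conventions

Rasters are rectangular float grids with an upper-left origin, square
pixels in metres, and NaN as nodata, in a planar metric CRS (geographic
data must be projected upstream). Text I/O uses ESRI ASCII grids.

* NDVI/EVI: per-pixel band algebra; zero denominators and nodata inputs
  propagate as nodata; NDVI is clipped to [−1, 1].
* Vegetation volume: height × pixel area on vegetated pixels, nodata
  elsewhere; negative heights (sensor artefacts) are clipped to 0 with a
  warning.
* Block aggregation requires an integer resolution ratio and an evenly
  tiling grid; non-integer ratios are rejected rather than resampled,
  keeping the operation exactly invertible in tests. Nodata is ignored in
  means; all-nodata blocks stay nodata; sum-aggregation conserves totals.
* **Pixel-in-buffer rule**: a pixel belongs to a circular buffer iff its
  centre lies within the radius — all-or-nothing edge pixels, matching
  common raster-extraction defaults. Buffers clipped by the raster edge
  produce a value from the available pixels plus a coverage warning.
* **Volume density denominator**: the number of in-buffer pixels × pixel
  area, not πr², so numerator and denominator share one discretisation.
  Nodata (non-vegetated) pixels contribute zero volume but count toward
  the area — sparse canopy is not inflated by missing pixels.
* **Zero-density logs**: densities ≤ 0 are logged as ln(density + ε) with
  ε = 10⁻³ × the smallest positive density observed, with a warning. The
  same flooring rule (clip at ε before the log) applies when the Shannon
  model log-transforms a non-positive buffer NDVI.

## Site selection

Candidate cells come from the NDVI map mean-aggregated to 100 m with
negative values then zeroed (aggregate first, zero second — the order
matters for mixed blocks and is tested). Five 3 km rings around the city
centre cross five equal-width NDVI bins (interior bin edges belong to the
upper bin; the last bin is right-closed). Within each ring × bin stratum,
up to two cells are drawn uniformly without replacement, rejecting draws
closer than 300 m to *any* already selected cell across strata (the
separation wording reads as a global constraint). Selection is greedy in
random order with a retry cap; under-filled strata are reported, never
padded. The fraction of a cell inside the city boundary is estimated on a
10 × 10 subgrid of the cell (bounded error, no exact polygon–cell
intersection); cells more than 25% outside are ineligible. Field-work
snapping of points to street furniture is not modelled: the cell centre is
the site.

## Diversity models

For each metric (richness, total VAR, Shannon), predictor (mean NDVI or
log vegetation-volume density) and buffer radius, an OLS model

    metric ~ week + distance_km + vegetation_b

is fitted, with week a dummy-coded categorical block (first level as
reference), distance to the city centre in km entered linearly, and the
vegetation term per radius *b*. NDVI enters the Shannon models
log-transformed (natural log, configurable); vegetation volume is always
log density.

* **Partial R²** of a single-column term is t²/(t² + df_resid); the
  multi-column week factor uses the nested-model form
  (R²_full − R²_reduced)/(1 − R²_reduced). The two forms agree to 1e-10
  for single columns (tested).
* **Buffer selection**: per metric × predictor the argmax-partial-R²
  radius is recorded; the modal argmax is chosen, ties broken by the tied
  radius with the highest mean partial R².
* **Predictor comparison** reports mean R² per predictor and the relative
  gain under both conventions, (a−b)/b and (a−b)/a, because "x% more
  variance" is ambiguous; nothing is hard-coded.
* **VIF screening** iteratively drops the worst column with VIF ≥ 5
  (constant columns have infinite VIF and go first).
* **Moran's I** uses inverse-distance weights w = 1/d (duplicate
  coordinates are an error, with advice to jitter), the analytic null mean
  −1/(n−1), and a two-sided permutation p-value with the (r+1)/(n_perm+1)
  estimator — permutation p-values are never exactly zero.
* Assumption diagnostics are emitted, never gates: models are reported
  with residuals and fitted values for plotting.

## Ordination

Bray–Curtis dissimilarities are computed after ln(1 + x) of the VAR matrix
(damping highly vocal species); the presence–absence cross-check uses
Jaccard. No automatic transformation happens inside the NMDS itself.

The NMDS minimises Kruskal stress-1 by alternating isotonic (monotone)
regression of configuration distances on the dissimilarities with Guttman
majorization updates; regressing on the dissimilarity values gives
averaging treatment of ties. Updates are accepted only if stress-1
decreases, so each start's stress trace is monotone. One start is
initialised from classical scaling (principal coordinates), the rest at
random; the lowest-stress solution wins, and convergence is declared when
the two best starts agree under Procrustes (m² < 1e-4). Final scores are
centred and rotated to principal axes; species scores are VAR-weighted
averages of site scores. Alongside the stress the result reports the
squared correlation between monotone-fitted and configuration distances
(`linear_r2`) — one common "goodness" readout, clearly labelled, since
published ordination R² values are often ambiguous between estimators.
Cross-checked against R vegan (`metaMDS`/`envfit`/`mantel`/`protest`)
during development: Mantel r agreed to 4 decimals, stress and envfit r²
within a few percent (different optimizers).

* **envfit**: continuous variables are regressed on the (centred) scores;
  the unit coefficient vector is the arrow direction and r² is the squared
  correlation between variable and fitted values. Factors get level
  centroids with r² = 1 − SS_within/SS_total of the scores. Significance
  by row permutation, (r+1)/(n+1).
* **Rotation to a variable** (display only): a rigid rotation sending the
  fitted direction of the variable (typically NDVI) to the first axis;
  distances and stress are unchanged.
* **Habitat annotation** from an AVONET-style trait table, with pooled
  classes: rock → human-modified (urban cliff-dwellers), coastal →
  human-modified (inland study area), riverine/wetland → aquatic,
  grassland/shrubland → open; unknown labels are an error.
* **Procrustes/PROTEST**: both configurations centred and scaled to unit
  sum of squares, optimal orthogonal superimposition (reflections
  allowed); m² is the residual sum of squares, t = √(1 − m²), p from row
  permutations. **Mantel**: Pearson correlation of lower-triangle entries
  with simultaneous row/column permutation of the second matrix,
  one-sided.

## Prediction and evaluation

The train/test split is simple random (no stratification by ring or bin),
⌈0.8 n⌉ training rows — 69/17 at n = 86. Prediction grids evaluate the
fitted linear predictor at each 100 m cell's NDVI and distance, averaging
over the week levels (the temporal block is a nuisance; averaging the
dummy effects equals averaging per-level predictions, and the result is
invariant to level order — tested). Cells whose NDVI falls outside the
training range are flagged as extrapolation but still predicted, never
clipped. Evaluation reports RMSE and MAE on the held-out sites and a
standardized major axis regression of predicted on observed values
(slope = sign(r)·s_y/s_x, symmetric in x and y), with the standard SMA
slope CI slope·(√(B+1) ± √B), B = (1−r²)·F₀.₀₅(1, n−2)/(n−2).

## Synthetic data: what it emulates, and what it does not

`syngen` generates, with one seed controlling everything:

* **NDVI surface**: base 0.25 + 0.05/km radial gradient away from the
  centre + a Gaussian random field (white noise convolved with a Gaussian
  kernel; correlation length 30 m, sd 0.25), clipped to [−1, 1], on a
  5 km × 5 km grid at 10 m resolution. The correlation length is set to
  urban-fabric scale (street trees, gardens, courtyards) so that buffer
  means at neighbouring radii remain distinguishable, and the base is
  chosen so buffer-mean NDVI at sites is essentially always positive, as
  in real temperate-city data.
* **Canopy**: height = 30 m × logistic(NDVI; centre 0.4, scale 0.12),
  multiplied by a smooth lognormal patch field (sd 0.5, 250 m patches)
  representing vegetation type varying independently of greenness (lawns
  vs shrubs vs trees), plus 1 m pixel noise. The patch field is essential:
  without it, log vegetation volume is an affine function of NDVI and the
  two predictors could not be ranked. The vegetated mask is NDVI > 0.2;
  height is nodata off-mask.
* **Sites**: 86 points ≥ 300 m apart, ≥ 850 m from the landscape edge (so
  the 800 m buffer stays on-grid), with recording effort ~N(6.49, 1.11²)
  days truncated to [3, 7] and one of four recording weeks in rotation.
* **Species**: Gaussian niches on the NDVI axis, centres spread over
  [0, 1], widths 0.15–0.35, peak per-period vocal activity 0.05–0.6;
  habitat class assigned from the niche centre (monotone from
  human-modified to forest). Occupancy and activity share the same niche
  response — a one-parameter-per-species simplification.
* **Detections**: per occupied site × species, each quarter-hour period
  contains ≥ 1 detection with probability q = activity × niche response;
  counts within an occupied period are 1 + Poisson(1); detection times are
  uniform within their period (VAR only depends on period occupancy).
  Confidences are Beta(8, 2) for true detections and Beta(2, 4) for an
  optional fraction of injected noise rows, so the 0.8 filter is exercised
  in both directions; single-detection species–site pairs can be injected
  to exercise singleton removal. Per-site effort truncates each stream.

Closed-form expectations (richness = Σ occupancy, VAR = Σ occupancy·96·q,
Shannon from expected VAR shares) serve as the analytic oracle for
Monte-Carlo consistency tests.

Not emulated: detection-distance decay (exposure is tied to the site's
buffer NDVI only; no detection radius), weather or diel/seasonal activity
cycles beyond the week label, audio itself, species interactions, and
observer/classifier error structure beyond the confidence mixture. Tests
passing on these simulations therefore demonstrate that the *estimation
chain* recovers known structure under the model's own assumptions — not
that the ecological model is true of any real city.

## Validation experiments (study conditions)

The experiments in `birdscape.experiments` fix the study conditions at
86 sites in the default 5 km landscape, responses generated from
100 m-buffer NDVI with signal-to-noise 1 (model R² ≈ 0.5, matching the
published regime for this kind of data), week-block effects at 20% of the
signal sd, and the Shannon response generated on the ln-NDVI scale — the
same functional form its model fits. Replicate counts: 500 for CI
coverage (design held fixed; OLS coverage is conditional on the design),
100 for scale recovery and predictor ranking (fresh landscape per
replicate), 200 null simulations per permutation test at 199 permutations.
These sizes keep the full validation run at about a minute on one core
while leaving the binomial noise well inside the tolerance bands.

## Known limitations

* Bray–Curtis is a semimetric; triangle-inequality violations are allowed
  (only boundedness and symmetry are enforced).
* The NMDS optimizer is SMACOF-style with a conservative
  accept-only-if-better rule; on hard instances vegan's monoMDS sometimes
  finds slightly lower stress (a few percent in development comparisons).
* `aggregate` refuses non-integer resolution ratios; resampling and
  reprojection are out of scope.
* The stratified selector is greedy with rejection; it reports, but does
  not optimise away, under-filled strata.
* Standalone `predict`/`evaluate` subcommands refit from tables rather
  than deserialising a stored model object.
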