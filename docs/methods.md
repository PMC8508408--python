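# Methods

This note documents the models, defaults and numerical choices behind
`mrscore`, and what the synthetic-data tests do and do not demonstrate.

## Scoring model

Institutions are graded by canonical category into levels 1–3. The
composite score for a city is

    MRSc = 100 * (W_1 S_1 + W_2 S_2 + W_3 S_3),

with `S_1`, `S_2` the city's level count divided by the national maximum
city count at that level, and `S_3` the city's per-capita level-3 rate
divided by the per-capita rate of the *reference* city — defined as the
city holding the maximum raw level-3 count, not the maximum rate. Two
consequences are deliberate and preserved:

* `S_3` may exceed 1 (a small city with a dense clinic/pharmacy network
  out-rates a populous reference city). The raw weighted composite
  (`mrsc_raw`, ≤ ~1) is retained alongside the ×100 display value.
* Ties at a level maximum share `S_i = 1`; rank ties share the smaller
  rank ("min" method) and output order is deterministic (rank, then city
  code).

Default weights are the Delphi consensus 0.6/0.3/0.1; the alternative
elicitation outcome 0.5/0.3/0.2 can be supplied via the grading-scheme
YAML. Weights must be strictly positive and sum to 1 — the tallies never
depend on them.

Units under a separate hospital-rating system (flagged `excluded`, by
default Hong Kong and Macao) are accepted at ingest but excluded before
normalization maxima, scores and ranks are computed: the default national
frame therefore ingests 369 units and scores 367.

## Cleaning

Two artefacts of point-of-interest feeds are handled:

* **Contaminants.** Records resolving to the animal-medical category are
  dropped before grading (category resolution: subcategory label first,
  then major label, after trimming and case-folding, through an editable
  synonym table).
* **Campus duplicates.** Large top-tier hospitals appear as several points
  (one per department). Within the 3A category only, points connected by
  chains of pairwise haversine distances ≤ 200 m (inclusive) are merged —
  single-linkage connected components, the unique order-independent
  reading of "merge nearby points". The kept representative is the member
  with the smallest id (a real input record, not a centroid), making the
  operation idempotent and invariant to row order. A grid index at the
  merge radius bounds the pairwise work; tests require exact agreement
  with a brute-force O(n²) oracle. Geodesic (haversine, mean Earth
  radius) distance is used; at 200 m the difference from any projected
  metric is far below the decision threshold.

## Equity statistics

The provincial primacy ratio is `R = M_1 / M_2` for the two highest
city scores in a province; provinces with fewer than two scored cities
(municipalities, single-unit regions) are reported not-applicable.
`R ≥ 2.0` (inclusive) flags over-concentration. The primate city is
defined purely by score, never by capital status.

Regional summaries report per sector / economic zone / province the unit
count, mean score and coefficient of variation. CV uses the sample
(n−1) standard deviation by default and is switchable to the population
flavour; single-unit regions report CV as not available. Both R and CV
are invariant to positive rescaling of all scores, which the tests
assert. The Northeastern sector and the Northeast economic zone contain
the same three provinces, so their summaries must coincide exactly — a
built-in cross-check of the region constants.

## Spatial methods

**Projection.** GWR and KDE operate in a planar metre metric obtained by
an azimuthal-equidistant projection about the point-set centroid (spherical
formulas, mean Earth radius). Distances from the centre are exactly
great-circle; pairwise distortion at within-country scale is small
relative to the bandwidths involved.

**KDE.** `f(p) = Σ_i φ((p − p_i)/h) / (n h²)` with φ the bivariate
standard Gaussian density and `n` the *total* point count — the standard
estimator, so the surface is a probability density (numeric integral 1 ±
2 % at adequate resolution; the auto-grid keeps cells ≤ h/2, capped at
1024² cells). A non-standard variant that normalizes by the number of
points within `h` of the query is available behind
`local_count_normalization=True`; it is not a density and is off by
default. The raster is written as an ESRI ASCII grid (plain text).

**GWR.** At each location the coefficients solve weighted least squares
with the fixed Gaussian decay kernel `w_ij = exp(−d_ij²/b²)` — note the
deliberate absence of the conventional ½ factor, and a fixed (not
adaptive) bandwidth; changing either would change every AIC value.
Per location the fit reports the fitted value, residual, internally
studentized residual `ε̂_i / (σ̂ √(1 − S_ii))` (with `S` the hat matrix;
a numerically perfect fit reports zeros rather than amplified rounding
noise) and the local weighted R² (clipped into [0, 1] with a logged count
of clips). Bandwidth selection minimizes the corrected AIC

    AICc = 2n ln σ̂ + n ln 2π + n (n + tr S) / (n − 2 − tr S)

by a coarse log-spaced grid followed by golden-section search in
log-bandwidth; the trace of evaluations is returned, and a non-unimodal
trace falls back to the global trace minimum with a warning. Local
designs with condition number above 1e12 raise a numerical error naming
the location. As `b → ∞` all weights approach 1 and the fit reproduces
global OLS to 1e−6 (tested against statsmodels); per-location solutions
are tested against statsmodels WLS.

**Moran's I.** Residual randomness is tested with row-standardized
k = 8 nearest-neighbour weights, expected value −1/(n−1), and a
directional permutation pseudo p-value (999 seeded permutations, tail on
the side of the observed statistic — the permutation-test convention of
the spatial-analysis literature, with minimum attainable p of 1/1000).
Constant inputs are reported not-applicable.

## Synthetic data generator

The generator emulates the statistical structure of a national facility
feed at the 2019 study frame: 31 mainland province-level units with
realistic per-province city counts plus two excluded units (369 total,
367 scored). Defaults, chosen once as the study conditions:

* **Population** log-normal, log-mean 14.8 and log-sd 0.8 (median city
  ~2.7 M, heavy upper tail); **GDP** = 70 000 · pop^1.1 per-capita base
  with log-normal noise of log-sd 0.8, reflecting the near-order-of-
  magnitude spread of per-capita output across cities. GDP, not
  population, drives high-tier institution allocation (below), so the
  composite score is more strongly explained by GDP than by population —
  the contrast the downstream GWR is expected to detect.
* **Level rates per capita** 1.46e−6 / 1.27e−4 / 7.38e−4 for levels
  1/2/3 — the national level counts (1,981 / 172,983 / 1,001,055)
  divided by the expected synthetic national population, so the expected
  level mix reproduces the published 0.17 / 14.71 / 85.12 % shares.
* **Level-3 counts** are Poisson around rate × population × mean-1
  log-normal noise. The noise log-sd is set in closed form to hit a
  target population–count Pearson correlation (default 0.81): for
  log-normal populations with log-sd s_p,
  `r = sqrt((e^{s_p²}−1)/(e^{s_p²+s²}−1))`, hence
  `s² = ln(1 + (e^{s_p²}−1)/r²) − s_p²`. Poisson noise is negligible at
  the default counts (~2,700 per city).
* **Levels 1–2** distribute the national expected total over cities by
  GDP weight, with each province's primate (largest-population) city
  weight multiplied by `primate_boost` = 4 and weights renormalized —
  concentrating high-tier resources in primate cities while preserving
  the national expectation exactly. Excluded units receive no 3A
  hospitals (separate rating system).
* **Contamination**: 63 % of level-1 points get a clone at a uniform
  geodesic offset of 5–195 m (safely inside the 200-m merge radius), and
  animal-medical records amounting to 2.7 % of the valid count are
  added — both ratios matching the published cleaning arithmetic
  (1,250 duplicates per 1,981 kept 3A points; 31,539 contaminants per
  1,176,019 valid points).
* **Geometry**: province centres on a jittered grid over a country-scale
  lon/lat box; cities Gaussian around province centres; points isotropic
  Gaussian (default sd 5 km) around city centroids. The within-city
  spatial distribution is a modelling choice of this package — only
  within-city distances at the 200-m scale need to be realistic for the
  pipeline.

All randomness flows from one root seed; identical (seed, config) yields
byte-identical tables. Ground truth (per-city level counts, injected
clone and contaminant ids) is returned for every dataset.

The GWR test harness (`generate_gwr_surface`) draws locations on the unit
square and a standard-normal covariate, with user-supplied smooth
coefficient surfaces and Gaussian noise, returning the true surfaces for
recovery testing (GWR must beat global OLS on coefficient RMSE).

**What passing tests do not show.** The generator reproduces marginal
structure (level mix, count–population coupling, primate concentration,
duplicate geometry), not real geography: no road networks, no
accessibility, no spatially autocorrelated covariate fields, and
city-level noise is independent across cities. Agreement on synthetic
data therefore validates the pipeline's algebra and algorithms, not any
empirical claim about a particular country's resource distribution.

## Problem sizes and runtime defaults

The default synthetic dataset has ~1.3 M facility points and generates in
~10 s; the unit-test suite uses reduced frames (tens of cities, hundreds
of points) except where the 369-unit default frame is itself the object
under test, and samples true level counts directly when point emission is
irrelevant. Oracle tests bound the brute-force work at ≤ 500 points
(dedup) and ≤ 400 observations (GWR).

## Known limitations

* Score normalization is relative to the within-dataset maximum city, so
  scores are not comparable across datasets or years without a fixed
  reference.
* The per-capita reference for level 3 follows the max-count city; a
  different (e.g. max-rate) convention would rescale `S_3` and is not
  offered.
* GWR uses a single fixed bandwidth for all locations (no adaptive or
  multiscale variant) and dense O(n²) linear algebra, adequate up to a
  few thousand analysis units.
* The Moran's I weight choice (k = 8 kNN) is a convention; substantive
  conclusions should be checked under alternative k.
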