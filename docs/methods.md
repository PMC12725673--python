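# Methods

This note documents the models, conventions and numerical choices behind
`vcclek`, and what the synthetic-data tests do and do not demonstrate.

## Survey data model

An interview yields, per fisher: village/port, interview year, age,
experience (years), gears, up to three target species, coded decline
drivers, and — for every decade of activity — a categorical catch-trend
score in {MD, D, S, I, MI} plus the percentage the fisher assigns to it.
Decades run 1980s–2010s; the 2020s are structurally excluded from the
enumeration (the survey design omits them to avoid pandemic-era bias), and
careers beginning before 1980 are tracked as a `pre1980s` flag.

**Active decades.**  The surveys report per-decade respondent counts but no
assignment rule, so membership is defined by career-interval intersection:
a fisher with interview year *t* and experience *x* is active in every
decade whose calendar interval `[d, d+9]` intersects `[t − x, t]`; partial
overlap counts.

**Eligibility.**  Analysis keeps consenting fishers with at least five
years of experience.  The threshold is *inclusive* (≥ 5): the published
per-village experience ranges bottom out at exactly 5 years, so a strict
`> 5` reading would contradict the study's own roster.  `inclusive=False`
gives the strict variant.

## Yamane sampling design

Per-village target sample sizes use `n = N/(1 + N·e²)` with `e = 0.10`.
Because sources disagree on `N`, the per-source *unrounded* sizes are
averaged; mean, minimum and maximum are each rounded half-to-even.  Missing
sources are skipped, never imputed as zero.  This rule reproduces 19 of the
20 published village rows exactly; an exhaustive search over per-source /
mean / extreme rounding-mode combinations shows no self-consistent scheme
reproduces all 20, so the one deviating printed mean (Cañaveral, printed 24
vs computed 24.51 → 25) is treated as a printed erratum — a one-unit typo
in its third source (39 → 38) would produce the printed value.  It is
recorded in `KNOWN_PRINTED_MISMATCHES` together with the same village's
internally inconsistent printed coverage percentage (164 % printed vs 171 %
from its own roster columns), and tests assert both discrepancies
explicitly rather than passing silently.

Coverage is `round(100 · interviewed / target mean)`.

## The VCC cascade

Per fisher and stratum, virtual catch starts at the anchor `X` and updates
once per decade by `V_k = X_{k−1}(1 + f_k)` with
`f_k = sign(Z_k) · Y_k/100`.  Design points:

* The update's sign is carried entirely by the categorical score; the
  elicited percentage is a magnitude in [0, 100].  Declines therefore can
  never push the index below zero.
* A missing percentage on a non-stable score is a hard error; an opt-in
  imputation mode substitutes configurable category midpoints (defaults in
  `MIDPOINT_PCT`).  The instrument always elicits percentages, so
  imputation is off by default.
* **Anchoring.**  Fishers active in or before the 1980s anchor at 1.
  Later entrants anchor at the cohort mean virtual catch of the decade
  preceding entry, computed decade by decade (1980s entrants first, their
  means then available to 1990s entrants, and so on) — well defined because
  baselines only look backward.  Anchors are computed *within the stratum
  being aggregated* (per-gear baselines for per-gear trends): mixing scales
  across strata would let a high-catch gear inflate another's baseline.
  `baseline_weighting=False` anchors everyone at 1, which quantifies the
  shifting-baseline bias (late entrants then appear systematically offset
  from veterans even when both experienced identical decadal changes; the
  acceptance suite demonstrates the offset and its removal).
* **Strata.**  `overall` uses the fisher's general perception when
  elicited, else the per-decade mean of their per-species signed fractions
  (flagged derived in the sense that it is computed, not elicited);
  `species:<s>` uses the per-species responses; `gear:<g>` subsets fishers
  by gear and uses their overall fractions.

Aggregation reports per-decade arithmetic mean, *sample* standard deviation
(n − 1; reported as 0 with n = 1), and cohort size.  Relative change is
`100·(new − ref)/ref`.  The trend line is an ordinary least-squares cubic
over decade indices 0–4 (index 0 = optional pre-1980s baseline point at
value 1); with four points the cubic interpolates, and no orthogonalization
is needed at this scale.  Driver ranking counts each fisher's coded labels
once, descending, ties alphabetical.

## Spatial stage

* Grid: cell-centre registered 0.01° lon/lat raster, row 0 at the northern
  edge; membership is "polygon contains the cell centre", which keeps
  deposition additive and admits an exact brute-force oracle (tests compare
  against exhaustive centre-by-centre containment).
* Effort surface: each fisher-decade polygon deposits 1; unit normalization
  divides by the maximum, so values are the share of the peak cell.  Core
  grounds are cells at ≥ 0.6 of a unit-normalized per-fisher surface
  (configurable).
* VCC surface: deposit is the polygon's VCC value; the additive surface is
  scaled by `4/max|v|`, preserving sign and zeros, so the extreme magnitude
  is exactly 4.  The display range is stated in the source material but not
  its formula; a min-max affine variant (`minmax_affine_symmetric4`) is
  provided as an alternative.  Both normalizations are idempotent, and an
  all-zero surface is returned unchanged with a flag.
* Centroids are planar (shoelace) in degree space.  At the near-equatorial
  latitudes of interest the displacement versus a projected centroid is far
  below hand-drawn polygon uncertainty for polygons up to ~2°.
* Distances are point-to-point WGS84 geodesics (self-contained Vincenty
  inverse; tests pin it to reference values from `geosphere::distGeo`, the
  routine used in the original spatial workflow, to < 1 cm).  The original
  workflow names a point-to-line routine while describing distances "to the
  port of origin"; point-to-port is taken as primary, and a
  point-to-polyline mode (`distance_to_polyline_km`) covers the
  coast-as-line reading.
* Self-intersecting input polygons are repaired by zero-buffering and
  flagged; degenerate (zero-area) polygons are rejected.
* Rasters are exchanged as ESRI ASCII grids (plain text, nodata −9999)
  with round-trippable `%.17g` floats; polygons as GeoJSON in EPSG:4326.

## Synthetic-data generator

`default_config()` encodes the study conditions: 22 villages, 65 fishers
per village (≈ 1,436 contacted), consent rate 1161/1436, entry-decade
probabilities chosen so the active-cohort fractions match the published
decadal respondent counts (≈ 30 %, 52 %, 79 % of retained fishers active in
the 1980s–2000s), per-decade score simplexes matching the published
polarity (66 % positive categories in the 1980s, 89 % negative in the
2010s), the published gear shares, and per-decade distance means
36.8 / 37.1 / 46.6 / 54.4 km.

Choices where the source reports no distribution:

* Perceived percentages: truncated normal per category on [0, 100], means
  at the published anchors (decline 25, major increase 70; major decline 60
  and increase 30 interpolate the anchor pattern), sd 10–15.  These are
  anchors, not fitted values.
* Distances: gamma with the stated mean and sd = 1.3 × mean, giving the
  strong right skew the published medians (≈ one third of the mean) imply.
* Polygons: randomly rotated rectangles (edge ~0.08° ± 0.04°) centred at
  the drawn distance due west of the port.  Ports sit on a meridian
  "coast", so the true distance is an analytic longitude offset, recorded
  per ground in the truth bundle.
* Villages draw from `SeedSequence.spawn` children: output is reproducible
  for a fixed seed and independent across villages.

What the generator does **not** emulate: spatial autocorrelation of effort,
bathymetry or seasonality, fisher behaviour (gear switching, species
turnover), inter-decade correlation of a fisher's scores, or recall error.
Passing recovery tests therefore show the *pipeline* is unbiased under the
assumed sampling structure — not that real interviews satisfy that
structure.

## Test problem sizes

The suite runs everything at desk scale: cascade equivalence is exhaustive
(all 5⁴ score sequences × a five-point percentage grid, ~780 k values);
Monte-Carlo recovery uses ~1,000 retained fishers (3-standard-error
bounds); generator fidelity uses 10,010 fishers; rasterization oracles use
25 polygons on a 50 × 50 grid.  The published aggregate trajectory
(1.46, 1.75, 1.73, 0.7) is a property of the deposited field dataset and is
not re-derivable from the printed tables alone; the suite instead verifies
the printed *relative changes* follow from those printed means, and
validates the cascade itself by oracle equivalence, parameter recovery and
the shifting-baseline experiment.

## Known limitations

* Strata trajectories assume responses cover contiguous decades from entry;
  gap-year careers (fishers who left and returned) are rejected rather than
  modelled.
* The 1990s/1980s distance-mean gap in the study conditions (0.3 km) is
  below Monte-Carlo resolution at n ≈ 10⁴ grounds; fidelity tests assert
  ordering only where the configured gaps resolve.
* Vincenty's inverse fails to converge for near-antipodal pairs and falls
  back to a spherical approximation (≤ 0.5 % error); irrelevant within a
  single EEZ but worth knowing for reuse.
* `coverage_ratio` can exceed 100 % by construction (snowball sampling can
  out-recruit the Yamane target); values are not capped.
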