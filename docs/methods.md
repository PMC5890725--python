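# Methods

`beetracker` implements the computational chain behind woodland surveys of
feral honey bee (*Apis mellifera*) colonies: locating nests from forager
flight data (beelining), decoding scout waggle dances on experimental
swarms, and turning counts into colony densities. This note documents the
models, their assumptions, the defaults, and what the synthetic-data tests
do and do not demonstrate.

## Geodesy

All geometry is spherical with R = 6,371,000 m. The study scale is under
10 km, where ellipsoidal corrections are below 0.5% — far smaller than any
field measurement error — so the simpler model wins on testability.
Bearings are degrees clockwise from true north in [0, 360); timestamps are
UTC (readers convert civil time via an explicit `utc_offset` column).

Planar work (ray intersection, disc unions) uses an equirectangular
`LocalFrame` centered on the data centroid; project/unproject round trips
move points by far less than 0.1 m within 10 km of the origin (tested).

Solar azimuth uses the NOAA solar-position equations (after Meeus):
Julian century → solar geometric mean longitude/anomaly, equation of
center, apparent longitude, corrected obliquity, declination and equation
of time, then hour angle → zenith → azimuth. Accuracy over 1950–2100 is a
few hundredths of a degree; the test suite cross-checks against an
independently coded Michalsky (1988) almanac algorithm (agreement well
under 0.5°, typically 0.001°) plus convention anchors (azimuth ≈ 180° at
local apparent noon in mid-northern latitudes, monotone increase through
daylight). The azimuth convention is north-referenced clockwise — the
near-universal one; a south-referenced convention would shift every decoded
dance bearing by 180°.

## Beelining

A trained forager's round-trip time t (minutes) at a feeder bounds the
nest distance through the empirical calibration

    d_max (m) = 243 · t − 627.75,

evaluated for the *fastest* bee at that feeder: handling time inside the
nest only lengthens trips, so the fastest bee is the least biased. Times
at or below the positive root (≈ 2.58 min) are reported as 0 m ("nest
adjacent to feeder") with a warning, never negative. The flight direction
is the circular (vector) mean of the observed vanishing bearings — an
arithmetic mean fails at the 0/360 wrap. Each feeder thus yields a
directed ray with a maximum range, or a range-only disc when no bearing
could be read beneath the canopy.

`NestLocalizationModel.fit()` combines constraints in the local planar
frame:

* **≥ 2 non-parallel rays** — the point minimizing the summed squared
  perpendicular distances to the rays (closed-form 2×2 normal equations);
  uncertainty is the RMS perpendicular residual. This generalizes the
  manual case-by-case reasoning of field practice into one estimator. If
  the solution falls outside the intersection of all range bounds it is
  pulled to the nearest point of that region (method tag `ray+range`).
* **1 ray (+ discs)** — the point on the ray at the tightest forward range
  bound; uncertainty is half the feasible ray segment.
* **discs only** — centroid of the disc-intersection region; uncertainty is
  the region's circumradius about the centroid. An empty intersection
  returns the least-violation compromise point, flagged inconsistent.

Range bounds are *soft*: round-trip times overestimate distance whenever a
bee lingered (e.g. danced) in the nest, so estimates beyond a bound are
clipped, not rejected. The clipping region gets ~1 m of slack so a nest
exactly at maximum range counts as inside (the 256-gon disc approximation
inscribes the true circle). Rays whose bearings all agree within 2°
(mod 180) and have no disc are refused as unlocalizable.

Estimates within a configurable merge radius (default 500 m, matching
re-detections of one colony across seasons) are merged by single-linkage
clustering, averaging locations and pooling supporting feeders.

The screened area is the union of 2,000 m buffer discs around the sampling
sites — 2 km being the radius honey bee recruitment normally covers —
computed as a shapely union of 256-gons (< 0.01% area error; the tests
compare against a Monte-Carlo rejection-sampling oracle at 1%). Density is
nests / union area, exact until report-time rounding to two decimals.

## Dance decoding

Circuit duration τ (s; mean over ~6 circuits) maps to distance through the
two-branch linear calibration fitted to von Frisch's original data:

    d (m) = 466.5495 · τ −  675.0336   for τ ≤ 3.15 s
    d (m) = 1102.7328 · τ − 2666.6256  for τ > 3.15 s

The breakpoint is read as *inclusive* on the near branch. The branches
disagree by 12.38 m at 3.15 s; the forward map is monotone overall, and the
inverse (used by the generator) snaps distances inside the 794.6–807.0 m
gap to the nearer branch endpoint. Durations at or below the near branch's
positive root (≈ 1.447 s) — and generator distances below the 100 m floor
of the calibration data — raise a calibration-range error. The published
forward regression line for the near range carries an intercept whose sign
is inconsistent with this inverse (−1.4552 printed where the inverse
implies +1.4469); the distance-from-duration form above is treated as
authoritative.

True bearing = (dance angle from vertical + solar azimuth at dance start)
mod 360; the advertised site is the destination point at that bearing and
distance from the swarm location. Decoded sites are never trimmed, however
far out they fall — swarm scouts genuinely advertise sites kilometers away.

Per-swarm distances are summarized by the median and the 95th percentile
with linear interpolation between closest ranks (the common default;
the percentile rule is undocumented in most field reports and shifts the
upper percentile by a few tens of meters at n ≈ 30–60). Cross-swarm
averages are arithmetic means of the per-swarm medians and percentiles.

Homogeneity across swarms uses Kruskal–Wallis H with tie correction
(scipy) and a chi-square p on k−1 df; the suite verifies H against an
explicit rank-sum formula and the p-value against full permutation
enumeration on small instances (documented tolerance 0.15 at n = 3+3+3,
where the chi-square approximation is coarse). Pairwise Dunn z-tests on the
pooled mid-ranks use the tie-corrected variance N(N+1)/12 − Σ(t³−t)/12(N−1);
unadjusted two-sided p-values are reported alongside Holm-adjusted ones,
since star-threshold conventions vary.

## Density estimation

The cavity-occupation estimate multiplies the mapped habitat-tree density
by the occupation rate of the inspected subset:

    D = (N_trees / A) · (occupied / inspected).

It carries an explicit lower-bound flag: colonies outside mapped woodpecker
cavities are invisible, and imperfect ground detection is not modeled. A
Clopper–Pearson 95% interval accompanies the occupation rate as an artifact
addition. Trees are the counting unit even when multi-cavity.
`extrapolate_population` scales a density band linearly to a forest area,
rounding to two significant figures at report time.

Survey-table summaries use the *population* standard deviation (divisor n)
and substitute left-censored entries ("<50") by their censoring limit —
the conventions that exactly reproduce published summary rows (sample SD
would differ by ~60 m on a nine-tree table). Distances round to the
nearest 10 m, densities to two decimals, only at report time.

## Synthetic data

Generators invert the inference rules and add noise with the structure the
analyses assume; with all noise at zero, generation followed by inference
is the identity (tested to < 1 m), which is the core correctness guarantee.

Defaults define the emulated study conditions and are not tuned per run:

| parameter | default | rationale |
|---|---|---|
| region box | ~11 × 10 km mid-latitude (51°N) | size/latitude of a large beech-forest study area |
| bees per feeder | 5 | a handful of marked foragers per station |
| bearing noise | von Mises, SD-equivalent 5° | compass reading of a vanishing bearing under canopy |
| handling time | exponential, mean 1 min | non-negative and right-skewed; dance-prone bees linger, slow bees never undercut the deterministic minimum |
| circuit-duration noise | Gaussian, SD 0.1 s | reading error on a mean over ~6 circuits |
| dance-angle noise | Gaussian, SD 10° | protractor alignment plus dance scatter |
| occupancy probability | 7/98 ≈ 0.071 | observed cavity occupation in beech forest |
| foraging radius | 2,000 m | recruitment range; feeders farther from any nest yield nothing |

All draws flow from one seeded NumPy generator per call, so outputs are
byte-identical under a fixed seed (tested through the CLI).

What the generators do **not** emulate: multiple colonies recruiting at one
feeder, feeder-to-feeder iteration of a real bee hunt, spatially clustered
cavities, weather, or dance-consensus dynamics. Passing recovery tests
therefore shows the estimators are correct under their stated assumptions,
not that field data meet those assumptions.

## Documented simulation bounds and problem sizes

* Median localization error with 5° bearing noise, 3 feeders at 1,500 m,
  5 bees per feeder: bounded at **200 m**, checked over 500 seeded
  replicates (observed medians sit well below the bound; the bound is the
  documented contract, not a fitted value).
* Localization error grows monotonically with nest range at fixed angular
  noise (60 replicates per range).
* Cavity-density estimator unbiasedness: 1,000 replicates of a 282-tree /
  180 km² / 98-inspected design, mean estimate within 5% of truth.
* Three-swarm homogeneity power: ≥ 80% rejections at α = 0.05 over 500
  replicates of 8-dance swarms at clearly separated ranges.
* Monte-Carlo area oracle: 400,000 rejection samples, 1% tolerance.

## Known limitations

* Spherical geometry only; no ellipsoid, no atmospheric refraction beyond
  the chosen solar algorithm.
* Ray localization treats rays as full lines in the least-squares step;
  direction enters through the range bounds, not the objective.
* The Kruskal–Wallis p-value is the chi-square approximation; exact
  permutation is test-only.
* Whether a located colony is feral or managed is not decided by the code;
  that remains a field judgment.
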