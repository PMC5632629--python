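# Methods

This package reimplements, end to end, the analysis chain used to describe
the diving behavior of satellite/archival-tagged sperm whales from 1-Hz
time-depth records, sparse Fastloc-GPS surfacings, and a bathymetry grid:
dive detection, phase segmentation with shoulder correction, twelve per-dive
metrics, PCA + Ward hierarchical typing with bootstrap stability, activity
budgets, hexagonal dive-density grids, and quartile-window classification of
satellite-summarized dives. Because no tag archives are publicly deposited
for this system, a synthetic-deployment generator with ground-truth labels
is a first-class part of the package and defines the conditions under which
everything is tested.

## Dive detection and phase segmentation

A dive is any maximal run of samples deeper than a surface threshold
(default 1.0 m — exact zero would fragment dives on noisy surface readings)
lasting longer than 1 min with maximum depth over 10 m. At 1 Hz, run length
in samples is run duration in seconds.

Phases come from the per-second depth rate r(t) = depth(t+1) − depth(t),
positive down (positive rate = descending). The bottom phase starts at the
first *boundary candidate* — a strict sign change of the rate from
descending to ascending, or the start of a run of at least 10 consecutive
zero rates — and ends at the mirrored candidate found from the dive's end.
|r| < 0.01 m/s counts as zero, guarding against sensor quantization. A
strictly V-shaped dive, which has no interior candidate besides the apex,
gets a single-sample bottom there. The three phases always partition the
dive's samples exactly.

Whales often stall briefly at shallow depth during descent or ascent; taken
naively these stalls become the phase boundary and corrupt the bottom
phase. The shoulder rule compares the first boundary candidate with the
next deeper one: writing p1 and p2 for their depths normalized by the
dive's maximum depth, if p1/p2 < 0.68 the first candidate is recorded as a
"shoulder" and the boundary moves to the deeper candidate, iterating to a
fixed point. The published rule gives the 0.68 constant but not the exact
form of the "proportional difference"; the ratio reading p1/p2 is used here
and isolated in one function (`_refine_side`) so it can be swapped.
Refinement never moves the descent end earlier nor the ascent start later.

## Locations and movement

Dives within 2 min of a GPS fix take that fix (nearest in time; the earlier
fix on an exact tie). Others are interpolated linearly in lon/lat between
the bracketing fixes, weighted by the dive start time's fractional position
between the fix times — linear interpolation is adequate at the
kilometre-scale spacing of fixes here. Dives more than 60 min from the
nearest fix, or without a bracketing pair, are excluded from all
location-dependent metrics. The dive's start time anchors every temporal
comparison (the instant within the dive is otherwise arbitrary; surfacing
time would shift interpolations by minutes at most).

Distances are haversine on a spherical Earth (R = 6371 km, error below
0.5% at study scale). Speed is the great-circle distance between
consecutive dive locations over the time between dive starts (a minimum,
conservative travel speed). Turning angle is the absolute change in initial
bearing across three sequential dives, wrapped into [0, 180] and reported at
the middle dive.

Seafloor depth is a nearest-cell lookup in a regular lon/lat grid
(reproducible across grid resolutions, unlike bilinear blending). When a
dive is deeper than the charted seafloor — location error, steep relief, or
poor chart data — the dive's maximum depth is assumed to be the true
seafloor, so distance-to-seafloor is never negative.

## The twelve metrics and transforms

Per dive: MaxDepth (m), DiveDur (min), descent and ascent rates (m/s,
phase-boundary depth differences over phase durations), BottDur (min),
mean and SD of bottom-phase depth (SD with the n−1 denominator;
single-sample bottoms get SD 0), post-dive interval PDI (min; missing for
the last dive of a record), BottFrac = BottDur/DiveDur, DistToSeaFlr (m),
Speed (km/hr), and turning angle TA (deg). Missing neighbors or invalid
locations yield missing values, never zeros.

Right-skewed variables take a square root (MaxDepth, rates, BottDur, mean
and SD bottom depth, DistToSeaFlr, Speed, TA); PDI takes log10 with values
floored at 0.03 min (the observed support minimum) so back-to-back dives do
not produce −inf; DiveDur and BottFrac are untransformed. Transforms
round-trip within 1e-9.

`flag_outliers` implements a 5-MAD univariate screen (raw MAD, ≈3.37 sigma
for a Gaussian column) with manual add/remove overrides. It is *not* wired
into the default pipeline: on strongly multimodal dive data a univariate
rule flags entire legitimate behavior types, where an analyst's manual
screen would remove only isolated artifacts (the archival study removed 4
dives of ~2,900, by hand).

## Typing: PCA, Ward, stability, names

The complete-case transformed table (dives missing Speed/TA/PDI or a valid
location are excluded) is centered and scaled to unit SD; the correlation
matrix is eigendecomposed and the smallest number of leading components
whose cumulative explained variance reaches 85% is retained (five, on the
canonical synthetic deployment — matching the dimensionality reported for
the real archives). Scores on those components feed agglomerative
clustering with Ward's minimum-variance criterion under Euclidean distance
(scipy linkage, equivalent to R's `ward.D2`), cut at six clusters.

Stability is assessed clusterboot-style: for each of B bootstrap resamples
(default 1,000; analyses here use 200 for speed), the resample is
re-clustered and each original cluster is matched to the resample cluster
with the highest Jaccard similarity over the points present in the
resample — best match, not a one-to-one assignment. Mean per-cluster
Jaccard near 1 indicates a stable cluster; below ~0.6, one that dissolves.
On the synthetic deployment the Mid-water and Variable clusters are the
least stable (≈0.55–0.66), the same qualitative pattern the original
archives showed.

Cluster naming is a post-hoc labeling convenience, not part of the
clustering: per-cluster medians run through a decision list with
configurable cutoffs derived from the published type summaries — shallow if
median MaxDepth < 30 m (Short- vs Long-shallow split at 5 min median
duration); otherwise Benthic if median DistToSeaFlr < 25 m, V-shaped if
median BottFrac ≤ 0.3, Variable if median SD of bottom depth > 40 m, else
Mid-water. Name collisions are returned with an explicit "ambiguous"
suffix rather than silently resolved.

Satellite-summarized dives carry only max depth and duration. Each type's
(Q1, median, Q3) of raw MaxDepth and DiveDur (linear-interpolation, R
type-7 quantiles — the convention matters because quartile edges shift
classification) define acceptance windows; a summarized dive inside both
windows of exactly one type takes that type, inside none is Unknown, and
inside several takes the type with the smallest sum over the two variables
of |value − median|/IQR.

## Budgets, surface periods, grids, diel labels

The activity-budget time denominator is the sum of all dive durations and
post-dive intervals; each type's time share uses dive durations only and
all PDI is pooled as surface time — exactly the accounting under which the
published per-whale rows sum to 100. A missing final PDI counts as 0.
Surface periods are gaps between consecutive detected dives, flagged beyond
30 and 60 min.

Dive locations are binned on flat-top hexagons (cell size = 5 km across
flats) in a Lambert azimuthal equal-area plane centered on the deployment
centroid, via exact axial cube-rounding — a partition, so counts conserve.
Day/night labels use local time = UTC plus a fixed offset (one study area,
no DST); night is [20:00, 07:00), half-open so 20:00 is night and 07:00 is
day. The diel contrast is descriptive — per-tag paired night−day
differences in mean MaxDepth with a sign-permutation p-value — since the
model-based version (mixed-effects regression) is standard-package
territory.

## The synthetic generator: what it emulates, and what it does not

Six dive-type templates are parameterized by the published per-type medians
of max depth, duration, bottom fraction, bottom-depth wiggle SD, and PDI.
Depths and durations are log-normal around the medians; each type's
multiplicative dispersion is calibrated from the published per-type min–max
ranges treated as ±3 sigma in log space, averaged over depth and duration
(Mid-water 1.39, Short-shallow 1.73, V-shaped 1.73, Benthic 1.25, Variable
1.32, Long-shallow 1.72). Profiles are piecewise: linear descent, a bottom
phase of smoothed Gaussian wiggle rescaled to the type's SD (so the realized
maximum equals the drawn depth), linear ascent. The Benthic template tracks
the local seafloor 0–5 m above it; the V-shaped template caps the bottom at
5% of the dive. The surface track is a correlated random walk (mean speed
3.5 km/hr, per-minute heading noise SD 25°, speeds clipped to the plausible
0.1–10.9 km/hr envelope) over a parametric seafloor (720-m basin, Gaussian
canyon to ~1,220 m, northern shelf under 400 m), started at the canyon edge
where local water depth is ~750 m. Fixes are attempted at each surfacing
from a Qualifying Dive (>10 min, >10 m), with a second attempt 5 min later
if the whale is still at the surface; Behavior Messages summarize four
consecutive Qualifying Dives (residuals at deployment end are dropped —
firmware behavior unspecified) with a shape code derived from bottom
fraction (V < 0.2 ≤ U < 0.5 ≤ Square), an invented stand-in since the
transmitted shape algorithm is not publicly documented.

Deliberate idealizations, and what passing tests therefore do *not* show
about real data:

- Every generated dive is detectable (max depth ≥ 10.5 m; duration ≥ 75 s,
  so the detectable run stays over 60 s after the sub-1-m lead-in/out is
  trimmed). Real records contain sub-threshold submergences; detector
  recall of 100% on synthetic truth says nothing about those.
- Depth and duration are drawn independently within type, whereas real
  dives correlate them through travel time; simulated rate spreads are
  accordingly wider.
- The bottom-wiggle SD is fixed per type, making SD of bottom depth nearly
  deterministic within type; real per-type SD ranges span two orders of
  magnitude.
- Benthic bottoms use one seafloor value per dive, so their realized
  bottom-depth SD (~1.4 m) understates the published 6.9 m median, which
  reflects whales tracking sloping bathymetry within a dive.
- The track is independent of dive type, so Speed, TA, and (largely) PDI
  carry no type signal and act as noise dimensions in the typing — a
  conservative choice for recovery tests.
- Surface noise is uniform on [0, 0.5] m; there is no sensor drift, and
  zero-offset correction is out of scope.

On the canonical 1,200-dive deployment (200 per type, seed 42) the full
pipeline recovers the generated types with adjusted Rand index ≈ 0.83 and
names all six types uniquely; the residual error is almost entirely
Mid-water/Variable confusion, consistent with those clusters' low bootstrap
stability. The satellite-message classifier reproduces the dominance of
Benthic and Variable agreement over the other deep types, but under the
range-calibrated dispersions the V-shaped quartile windows are wide enough
to absorb out-of-window Mid-water dives, so Mid-water agreement falls below
V-shaped — the reverse of the archival ordering, whose V-shaped windows
were evidently narrow relative to the printed range. A two-parameter
lognormal calibrated to the printed extremes cannot reproduce that shape;
the corresponding acceptance check is left failing rather than recalibrated
post hoc.

## Problem sizes and numerical choices

Analyses and tests use the 1,200-dive deployment (~2.4 M samples, ~28
simulated days), chosen to exercise every stage at realistic scale while
keeping any single run in seconds. Bootstrap stability uses B = 200 in the
drivers and B = 100 in tests (B = 1,000 remains the library default).
Quantiles are linear-interpolation (type 7); ties in fix assignment go to
the earlier fix; eigenvalues are clipped at zero before normalization;
degenerate inputs (empty fix lists, single-member clusters, single tags,
empty bottom phases) return missing values or degenerate intervals rather
than raising.
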