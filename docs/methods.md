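# Methods

This note documents the models, the synthetic study system, the
numerical choices and the limits of what the test suite demonstrates.

## The study system being emulated

Two closely related petrel species breed on neighbouring islands of one
archipelago with a two-month offset in their breeding calendars
(species A roughly April–October, species B June–December).  Both are
pelagic central-place foragers: during incubation they leave the colony
on multi-day trips over a large subtropical ocean region, alternating
fast directed *transit* flight with slow tortuous *search* behaviour
over foraging patches.  Their flight is wind-assisted, so trip speed
depends on the wind vector relative to the direction of travel.  The
analysis chain asks how the two species partition space, habitat and —
through a counterfactual simulation — whether the seasonal windscape
explains the breeding offset.

## Synthetic world

All estimators are tested as recovery problems against a generator with
known truth.  Default problem sizes were chosen as the smallest at which
the estimators' sampling noise is clearly below the test tolerances.

**Wind field.**  u/v wind (m s⁻¹) on a regular lon-lat-time grid over
60°W–10°W × 20°N–55°N.  Scalar speed is a smooth positive spatial
pattern (unit mean; low-order random Fourier modes) times a seasonal
profile `mean_speed + amplitude · sin(2π t / year)`; direction is a
smooth time-constant field.  Defaults: mean 8 m s⁻¹, amplitude
3 m s⁻¹ — the difference between the windiest and calmest month of the
generated field then falls between 4 and 8 m s⁻¹, a contrast of the
order seen between early- and late-season subtropical North Atlantic
conditions.  The grid defaults to 1° / 6-hourly, which keeps a full
year at ~40 MB; the type supports 0.25° / hourly grids for smaller
windows.  Written as classic NetCDF (`u10`, `v10` over time/lat/lon).

**Land.**  An analytic coastline: a continental strip along the eastern
domain edge plus a ~30 km islet whose west coast touches the colony
(the colony sits on the coast, in a sea cell).  The gridded
`land_mask()` is a raster render of the point-wise test; the point-wise
test is authoritative.

**Trips.**  A 2-state Markov chain (transit/search) drives gamma step
lengths and von Mises turning angles.  Defaults: hourly steps of mean
30 km (sd 8) in transit and 10 km (sd 5) in search; turning
concentration kappa 8 (transit) vs 0.7 (search); transition matrix
[[0.9, 0.1], [0.15, 0.85]] starting in transit.  Homing is a pure
heading bias: after 60% of the trip the heading is progressively
rotated toward the colony (fully from 85%), with an urgency override
when the remaining steps barely cover the distance home, and the final
step snaps to the colony when within reach.  Step *lengths* are never
altered by homing, so state-conditional step moments converge to the
truth; turning angles in the homeward segment, however, are biased
toward the colony bearing.  For estimator-recovery tests the generator
therefore offers `homing=False` (the pure switching process); pipeline
and integration tests use homing trips.  Steps landing on land are
redrawn up to 20 times (the second ten with uniformly random headings,
so coastal traps have an exit); then generation fails loudly.  Short
trips are generated as smaller-scale copies (12% of the step lengths,
a quarter of the steps) — the field's understanding of short trips is
limited, and this is an assumption, not a claim.

**Geolocator year.**  Daily positions follow a smooth annual cycle:
near the colony while breeding, displaced ~20° SW while not, with
per-bird AR(1) wander (sd 2°) and independent Gaussian location error
(default 1°, the scale of light-level geolocation).  A second species
generated with `phenology_lag_months=2` has the same spatial cycle
delayed two calendar months — this is the construct that makes the
breeding-synchronization counterfactual testable: aligning the
calendars must raise spatial overlap.  Daily wet (immersion) fractions
are Gaussian around 0.30 while breeding and 0.51 while not (clipped to
[0, 1]); during non-breeding the wet fraction falls on moonlit nights
(coupling 0.10, centred so the phase mean is preserved), emulating
nocturnal flight activity peaking at full moon.  Colony-attendance
days (30% of breeding days) are flagged and excluded from at-sea
means.

**Isotopes.**  δ13C/δ15N as additive species + year effects plus
Gaussian noise; defaults (species offsets +0.6/+1.2‰, year offset
+0.5‰ on δ15N, noise 0.3‰) give clearly detectable contrasts at
n = 25 per group.

**Seeds.**  Every generator derives its stream as
`default_rng([seed, tag])` with a fixed per-generator tag, so one
global seed yields independent, reproducible streams.

## Track preprocessing

Raw fixes are linearly interpolated in lon/lat onto exact multiples of
the 1-h or 2-h resolution (no extrapolation beyond the first/last fix);
points without a raw fix at their exact timestamp are flagged imputed.
Interpolating in geographic coordinates slightly distorts long steps,
acceptable far from the poles at these step lengths.  A raw gap wider
than 12 h (configurable) rejects the trip — a deliberate guard, since
heavy imputation would contaminate the step-length distributions.
Great-circle distances use the haversine on a 6371-km sphere (1°
latitude = 111.19 km).  Trips are classified long/short by k-means
(k = 2, 10 restarts, fixed seed) on standardized (max colony distance,
duration); standardization makes labels invariant to units, and the
cluster with the larger centroid norm in original units is "long".
Only long trips are analysed further.

## Behavioural HMM

Emissions: gamma on step length (parameterized by mean/sd), von Mises
on turning angle, centred at zero by default (turning-angle centres can
be estimated but rarely help).  The first step of each trip has no
turning angle and contributes only its step density.  Zero step lengths
are floored at half the smallest positive step to stay inside the gamma
support.  The likelihood is the scaled forward recursion (exact, tested
against exhaustive path enumeration to T = 8); trips contribute
independently.  The initial distribution is tied to the stationary
distribution of the transition matrix.  Fitting maximizes the forward
log-likelihood directly (L-BFGS-B on log/logit-transformed parameters)
from 10 perturbed quantile-based starts by default; label switching is
resolved by ordering states by gamma mean (transit = larger).  A fit
whose two step-length densities overlap by more than 0.5 (overlap
coefficient) or whose Viterbi path leaves a state under 2% occupancy
triggers a single-state warning.  Decoding is log-space Viterbi with
ties broken to transit.

Two fits per species mirror the pipeline's two uses: a 2-h fit supplies
"search" presences to the habitat model, a 1-h fit supplies "transit"
steps to the wind model (only tracks at a common resolution are
compared across species).

## Space use

Per-individual UDs are isotropic Gaussian kernels in degree space
(h = 2.25° per axis ≈ 250 km) evaluated on a 0.25° grid and rescaled to
sum to one; individuals are averaged per species × 2-month window
(Sep-Oct through Jul-Aug) and renormalized.  Working in degree space
matches a bandwidth stated in degrees; the ~11% cos(latitude)
anisotropy across the domain is accepted and documented.  Core areas
are raster masks: cells ranked by density, accumulated to 50% (or 75%)
of mass — polygonization is only used for GeoJSON export.  Overlap is
area(A∩B)/area(A) with cos(lat)-weighted cell areas; it is directional.
The synchronization counterfactual adds +2 calendar months to one
species' timestamps (day clamped to month end: 31 Dec → 28/29 Feb) and
reruns the identical pipeline.

## Habitat model

Presences are search-state locations; pseudo-absences are uniform
at-sea draws (3 per presence) from the disc around the colony of radius
110% of the species' maximum colony distance, intersected with the
combined range box of both species' tracks.  The boosting loop is the
staged procedure with cross-validated stopping: trees (depth =
tree-complexity, default 3) are fit to the gradient of the binomial
deviance with leaf Newton updates and row subsampling (bag fraction
0.75); for each fold the held-out deviance is recorded every 50 trees;
the size minimizing mean CV deviance is selected and the final ensemble
refit on all data at that size.  If CV deviance never falls below its
smallest-ensemble value the learning rate is flagged as too high.  The
default learning rate is 0.005 (demo configurations use faster rates
with correspondingly fewer trees).  Importance is the summed
squared-improvement of every split per covariate, normalized to 100%;
partial dependence is the data-average prediction with one covariate
swept.  Synthetic runs use five covariates (SST, distance to colony,
distance to seamount, wind speed, depth); arbitrary additional columns
are supported.

## Wind model

Transit ground speed (km h⁻¹) is modelled as
`log E[v] = β₀ + f₁(Δangle) + f₂(wind) [+ f₁₂]` with gamma variance and
log link (predictions always positive).  Bases are cubic B-splines,
8 functions per margin, with second-difference penalties plus a 0.05
identity shrinkage component so whole terms can vanish; the interaction
is the pairwise product basis with the Kronecker-sum penalty.  With the
log link and gamma variance the IRLS working weights are exactly one,
so each iteration is a penalized least-squares solve.  Smoothing
parameters (one for the margins, one for the tensor) are selected by
GCV on the converged working model over a 6-decade log grid.
Autocorrelation: lag-1 correlation of working residuals is estimated
within tracks (pooled), the working model is quasi-differenced per
track (Cochrane-Orcutt), and the cycle is iterated up to 5 times — an
approximation to a joint GLS fit that recovers an AR1 coefficient of
0.5 to within ±0.15 at n = 2000.  "Random effect" here means the AR1
blocks only; track-level intercepts are not estimated.  Predictions
outside the training box are clamped to it and flagged; surface
heatmaps mask cells with no nearby training data.

## Scenario simulation

For a focal species with fitted surface S, four scenarios cross
(own | other) tracks with (own | other) season.  Step geometry (length,
bearing) is never altered — total simulated distance is conserved
exactly.  Wind is sampled at each transit step's start location and
(possibly shifted) time; Δangle is recomputed from the observed bearing
and the counterfactual wind; speed = S(Δangle, wind); step duration =
length / speed; trip duration is the sum.  The percent change is
referenced to the mean observed transit duration of the focal species'
real trips.  Season shifts support whole-calendar-month offsets and,
by default in the pipeline, the day offset between the two species'
incubation date-windows (19 Jun vs 28 Aug starts).  Trips containing a
predicted speed below 1 km h⁻¹ are excluded with a diagnostic rather
than contributing unbounded durations.  Scenario pairs are compared
with Welch two-sample t-tests on per-trip durations
(Welch–Satterthwaite df); two identical constant samples are defined
to compare as t = 0, p = 1.

## Ancillary analyses

Moon illumination uses the mean synodic cycle (29.5306 d) anchored at a
reference new moon — day-level accuracy, which is all that aligning
activity peaks to full moons requires (the period check allows
29.2–29.8 d between maxima).  Isotope contrasts are two-factor
(species + year) OLS F-tests per isotope, with explicit zero-SS
handling so degenerate noise-free designs report F = ∞ (and identical
groups F = 0) instead of floating-point dust.  Wing loading is plain
mass/area: 300 g / 584 cm² = 0.51 g cm⁻², while 200 g / 460 cm² =
0.4348 → 0.43 at two decimals.  Isometric scaling returns
(ratio³ − 1)·100: a 10% wingspan gap implies 33%, far below the
observed ~50% mass gap — the arithmetic behind the wing-loading
contrast between the species.

## What passing tests do and do not show

The generators are deliberately idealized: wind direction is constant
in time; trips ignore wind drift entirely (the speed-wind relationship
enters only through the separately generated GAM training data);
geolocator error is Gaussian and season-independent, with none of the
equinox latitude degradation of real light-level data; immersion is a
daily Gaussian, not a within-day wet/dry sequence; isotopes are exactly
additive.  Passing tests therefore demonstrate the correctness of the
estimators and the internal consistency of the pipeline under the
stated models — not that real tracking data satisfy those models.
Quantities that depend on the real tracking datasets (trip statistic
tables, the published overlap percentages, variable importances and
t-statistics) are reproduced structurally, not numerically.

## Problem sizes

Recovery tests run at T = 2000 steps (HMM), n = 5000 steps (wind GAM),
n = 400–500 rows × 20 replicates (habitat null calibration), 4 birds ×
365 days × 2 species (space-use counterfactual) — sizes at which the
estimators' sampling error sits comfortably inside the asserted
tolerances while the whole suite stays fast enough to run routinely.
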