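# Methods

This note documents the models behind `petrelgls`: what each stage assumes,
the parameters that matter, what the simulator does and does not emulate,
and the numerical choices a user should know before trusting an output.

## Solar model

Declination, equation of time and apparent solar altitude use the standard
low-precision series (Meeus-style, as in the NOAA solar calculator). Over
1990–2050 the declination anchors (±23.44° at the solstices, zero crossings
on the computed equinox dates) and the equation-of-time extrema (−14.2 min
mid-February, +16.4 min early November) are reproduced to ≲0.1°/0.3 min,
far below the ≥1° longitude resolution implied by 5-min light bins.
Equinox dates are found by root-finding the declination on the UTC
timeline, so the equinox-exclusion window is self-consistent with the
latitude model rather than pinned to calendar dates.

## Threshold geolocation

**Twilights.** A dawn (dusk) is a rising (falling) crossing of the recorded
light through a device-unit threshold. Because each 5-min bin stores its
*maximum*, a rising signal attains the bin value at the bin end and a
falling one at the bin start; crossings are interpolated between the
correspondingly timestamped bins, which removes a half-bin (~2.5 min)
systematic day-length bias. Brief shading produces a spurious
opposite-kind crossing pair bounding a short segment; pairs bounding
segments under 60 min are deleted shortest-first, so a genuine crossing
truncated by one shaded bin survives. Same-kind crossings within 30 min
are merged and flagged `interrupted`.

**Calibration.** The sun-altitude threshold a₀ is the median solar
altitude, computed at the known colony, over all clean crossings in a
calibration window (≥5 twilights) while the bird attends the colony. With
the simulator's light transfer function the true value is −6.0°, recovered
to ±0.1° noiseless and ±0.3° under default noise.

**Positions.** Each dawn–dusk pair anchors a noon estimate, each dusk–dawn
pair a midnight estimate (reusing the preceding dusk): two per day.
Longitude: `lon = 15·(12 − EoT/60 − t_mid)` (midnight shifted 12 h),
wrapped to (−180, 180]. Latitude: the sunrise equation is solved on
φ ∈ [−89°, 89°] by a 0.5° bracketing scan plus Brent refinement; with two
roots the one nearer the running anchor wins. The anchor is the median of
the last five accepted latitudes (seeded by the colony), so one bad fix
cannot drag it away, and its jump allowance grows by 2°/day of gap so it
re-attaches after equinox windows.

**Degeneracy flags.** `lat_reliable` is false when (a) |declination| <
1.5°; (b) the band of latitudes whose predicted day length lies within
0.75° of hour angle (~6 min) of the observed one is wider than 10° — near
the equinoxes the day-length curve is nearly flat in latitude, and at high
latitudes this persists several days beyond the calendar window; or (c)
the chosen root is further from the anchor than 6° + 2°/day of data gap.
Flags (b) and (c) are what keep occasional equinox-edge solutions from
walking to −80° and corrupting range estimates; they are this package's
concrete reading of "the day-length equation is degenerate".

## Track processing

Latitudes within ±14 days of each computed equinox are excluded (the
window is closed at 14: day 15 is kept); longitudes are always retained,
because the transit-timing equation does not involve day length — on
stationary simulations the longitude error distributions inside and
outside the windows are statistically indistinguishable. The speed filter
is a forward single pass from the last kept fix, dropping fixes implying
>1500 km d⁻¹; it is the only spike-removal rule. Departure/arrival timing
through equinox windows uses raw daily longitudes: a *trigger* (first date
with |Δlon| > 5° sustained 3 days) and a back-dated *onset* (the day after
the last date within 2.5° of the colony longitude), the onset being what
phenology consumes. Trip metrics report both raw path sums (faithful to
how such totals are conventionally published, but inflated by position
jitter) and a 3-position running-median smoothed variant used for
parameter-recovery checks; equinox gaps are bridged by a single segment.

## Space use

The utilization distribution is a bivariate Gaussian kernel in unprojected
(lon, lat) degree space, sd = h = 1.8° per axis (~200 km at subantarctic
latitudes), evaluated at 1°×1° cell centres over the fixes' bounding box
padded by 3h, normalized so Σ density · cell_area = 1 (±1e−9). A contour
at level L is the minimal superlevel cell set: cells accumulated in
decreasing density order (ties broken lexicographically by (lat, lon))
until cumulative mass ≥ L/100 — exactly checkable against a brute-force
oracle, unlike interpolated isopleths. The 50% set is nested in the 95%
set by construction. The core centroid is the density-weighted mean of
50%-cells (unweighted variant available); longitudes are averaged on the
circle so date-line clouds centre near ±180°. Caveat of degree-space
kernels: a degree of longitude shrinks poleward, so cell areas in km² are
not uniform and h is isotropic in degrees, not km.

## Phenology

Days are UTC calendar days (deterministic without positions; at the
longitudes studied the offset from local solar days is below the daily
resolution of the metrics). Daily wet fraction is the exact ratio of wet
to total 30-s samples. Wing moult is the longest run of days with
smoothed (5-day centred mean; raw-day mode available) wet fraction > 0.9;
its "mean wing-moult date" is the density-weighted centre of the run with
weights (wet fraction − 0.9). Burrow attendance is a maximal run of fully
dry bins qualifying when its span plus one bin width exceeds 4 h — with
4-h bins one fully dry bin qualifies, since the true bout always extends
into the partially wet bins at each end and the rule cannot be applied
more finely than the bin resolution. Temperature corroboration requires a
bout bin ≥5 °C above the rolling 10-day median of each day's coolest bin
(robust to the warm burrow bins themselves); proximity corroboration
requires the nearest fix within a day to lie within 500 km of the colony,
using longitude-only distance when the fix has no reliable latitude.

The migration summary brackets last/first burrow occupancy around the
longest gap between accepted attendance events; departure/return come from
the distance rule (3-calendar-day smoothed daily positions beyond 200 km of
the colony, sustained 2 days) with longitude-onset fallback whenever an end
abuts an equinox gap, and are clamped to the attendance dates (a burrow
visit is direct evidence of colony presence). Outward/inward travel
durations run from departure (to return) to the first (from the last) kept
fix inside the 50% UD core — a documented choice; a distance-plateau
definition was the alternative. When the migration overlaps an equinox the
core-entry fix can only be observed after the window reopens, so these two
durations are biased long in such seasons; they are reported, not
recovery-tested.

## The simulator

`simulate` realizes the phase structure the analysis assumes: nightly
burrow attendance at the colony, a great-circle outward leg, a bounded
residency random walk (daily waypoints ~ N(destination, σ) with steps
clamped to the travel speed, linearly interpolated per minute), a
contiguous moult block, a great-circle inward leg, renewed attendance.
Light is a logistic function of solar altitude (dark floor −9°, saturation
+3°, midpoint −3°, unit scale: the default threshold of 3.99 units crosses
at exactly −6°), with lognormal multiplicative noise and per-bin shading;
burrow minutes are dark. Immersion is deterministic from the behaviour
states (2 samples/min); temperature is a linear function of latitude plus
noise, offset +8 °C in the burrow; feathers grow at truncated-exponential
times (mean 60 days over the post-breeding period, concentrating moult in
its first months) and draw δ values from linear latitude isoscapes whose
−19.5 ‰ δ¹³C isocline sits at 52° S (slope 0.45 ‰/°, residual sd 1.0 ‰;
δ¹⁵N: 9.9 ‰ at 52° S, slope 0.35 ‰/°, sd 1.2 ‰).

Default season (the reference conditions for recovery tests): colony at
49.47° S 69.95° E, deployment 1 February, departure after 26 attendance
days, ~2,450 km south-west to 64° S 40° E at 170 km/day (≈14-day outward
leg), 189-day residency with 60-km daily wander, moult peaking 35 days
after departure (25-day block), 7-day inward leg (≈350 km/day), return in
late September. Identical (config, seed) pairs are byte-identical after
serialization. Behaviour budgets: attendance and travel days are <70% wet,
plain residency ~83%, moult days 1380/1440 ≈ 96% wet — comfortably above
the 90% detection threshold so recovery failures indicate estimator bugs,
not simulator marginality.

What the simulator does *not* emulate: weather-driven multi-day shading,
sensor drift and clock drift, ocean currents or wind, variable flight/rest
microstructure, land masking, or position-dependent immersion noise.
Passing recovery tests therefore demonstrates estimator correctness under
the stated noise model, not field-grade accuracy: simulated position
errors (mean ~40–60 km) are several times smaller than the ~186 km
reported for real devices of this class, because real light curves are
corrupted by weather and behaviour in ways the lognormal-noise model does
not capture.

## Problem sizes in the test and acceptance suites

End-to-end recovery runs 50 full default seasons (seeds 1–50); the
structural-invariant sweep runs 200 seeds of a compact 85-day winter
season (same colony, ~1,000 km leg, no equinox overlap) — the invariants
being checked do not depend on season length, and the compact season keeps
the sweep at ~50 s. The acceptance script uses 20 default birds plus two
15–25-bird cohorts.

## Known limitations

- **Path length through equinoxes.** In a season spanning both equinoxes
  (the default), ~30% of migration days carry no usable latitude and are
  bridged by single segments, so any wander during those weeks is invisible:
  smoothed total-distance estimates run 20–35% below the true twice-daily
  path length, and no estimator operating under the exclusion rule can
  close that gap. Raw sums have the opposite bias (jitter inflation).
  Date, moult, centroid and range recovery are unaffected.
- Latitude reliability flags trade coverage for accuracy: at high latitudes
  they extend the effective latitude gap several days beyond the ±14-day
  calendar windows.
- The kernel is isotropic in degrees, not kilometres; at 64° S a 1.8°
  longitude bandwidth is ~88 km while the latitude bandwidth is ~200 km.
- Exact rank-test p-values enumerate up to n = 8 (Spearman) and n₁+n₂ = 12
  (Mann–Whitney); beyond that, seeded permutation or tie-corrected normal
  approximations are used.
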