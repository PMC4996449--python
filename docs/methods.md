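# Methods

## Data model

The unit of input is a vertical-profile record: one radar, one scan time,
one altitude bin (floor and width in m above the surface), with bird
density ρ_bird (birds km⁻³) and the migrants' ground-speed components
*u* (eastward) and *v* (northward) in m s⁻¹. Density derives from radar
reflectivity η (cm² km⁻³) as ρ = η/σ with σ = 11 cm², the
cross-calibrated radar cross section of a nocturnally migrating passerine;
the conversion is exposed (`reflectivity_to_density`) for pipelines that
deliver reflectivity rather than density. Missing measurements are `None`
end to end — a zero is always a measured zero. Two profile dialects are
fixed by this package (the raw table and the aggregated
`radar_id,interval_start_time,altitude_band,avg_u_speed,avg_v_speed,avg_bird_density`
table); timestamps are ISO-8601 UTC with a trailing `Z`.

## Screening and aggregation

1. Drop bins with floor < 200 m (ground clutter) and bins at or above the
   sampling ceiling (4000 m for EU-style 200-m bins, 3000 m for US-style
   100-m bins).
2. Retain *u*, *v* only where ρ ≥ 1 bird km⁻³ (inclusive); at lower
   densities the radial-velocity fit is dominated by residual rain and
   insects. The density itself is always kept, including for bins whose
   velocity was discarded — densities are meaningful below the velocity
   threshold and excluding them would bias band means upward.
3. Round scan times to the nearest 5 minutes (half-up; relevant for
   irregular US scan cadences, a no-op for data already on a 5-minute
   grid), then assign to half-open 20-minute windows anchored at the hour.
4. Average per (radar, window, altitude band): unweighted means over bins,
   bands assigned by bin floor (exact for 200-m bins against the
   200/1600/4000 m edges; a tie rule for 100-m bins). A density-weighted
   velocity mean exists behind `density_weighted` but is off by default —
   the screening is defined with plain means.
5. Zero-velocity convention: if a group measured velocities but none
   passed the threshold, the aggregate is *u* = *v* = 0 with a flag:
   "measured, no migration detected". In the aggregated CSV this datum is
   exactly the pair `0,0`; on reading, `0,0` is mapped back to the flag.
   A genuine nonzero-sample mean landing exactly on (0, 0) would be
   conflated — with floating-point means of real measurements this is a
   measure-zero event we accept for a six-column interchange format.

Aggregation is idempotent (aggregating aggregates at the same grid is the
identity) and insensitive to records below the clutter floor; both are
property-tested.

## Field reconstruction

Sites are projected with a spherical azimuthal-equidistant projection
centred on the network centroid (IUGG mean radius 6371.0088 km), giving
planar km coordinates; distances from the centre are exact and shape
distortion over a few hundred km is negligible for this purpose. The
original interactive tools interpolate in screen pixels; working in
projected km instead makes results independent of rendering resolution,
and pixels enter only in the render module.

For each 20-minute interval and altitude band, velocity at a point is the
inverse-squared-distance weighted mean of the k = 5 nearest vector-bearing
radar samples (w = d⁻²); density is interpolated identically from the
density-bearing samples. Zero-convention samples participate (they pull
the field toward rest around quiet stations); missing samples are simply
absent. Details that make the operator well defined everywhere: an exact
hit (d = 0) returns that sample's value; samples tied with the k-th
distance are all included, so results cannot depend on input order; with
no vector-bearing sample the field is *undefined* and callers render no
flow there. IDW with positive weights is a convex combination, so
interpolated values stay in the hull of the contributing samples and honor
measurements exactly at the radars — both property-tested against a
brute-force oracle.

In time the field is piecewise-constant per interval, matching the
stepwise updates of the animated visualization; linear blending between
consecutive intervals is available behind `time_blend` for smoother
animation and is off by default.

## Streamlet animation

A population of n = 450 streamlets is seeded uniformly over the view
domain with ages staggered uniformly below their lifespans. Per frame each
head moves by V(head)·Δt·s, the old head joins a trail whose segment
opacities decay geometrically (fade 0.95/frame), and a streamlet reaching
its lifespan is replaced by a fresh uniform seed, conserving the
population exactly. Lifespans are uniform in [30, 90) frames ("varying
lifespans"; no canonical value exists, so deaths de-synchronize without
long-lived outliers). Every 120 frames the engine advances one 20-minute
interval. The nominal animation rate is 60 frames per second; Δt = 10 s of
simulated time per frame makes 120 frames span one real interval, and a
speed exaggeration s = 30 (configurable) makes 10 m s⁻¹ flows read as
motion at a glance — the animation is deliberately faster than the birds.
Density is not encoded in this visualization. Trails older than 90 frames
(opacity < 0.01) are dropped for bounded memory. All randomness flows from
one seeded generator; replays are bit-identical, which the tests assert on
frame geometry and rendered GIF bytes.

## TIMAMP

The map area is a lattice of cell_km × cell_km cells (10 km for EU-style
cases, 20 km for US-style) snapped to multiples of the cell edge, keeping
cells whose centre lies within 75 km of the nearest radar — the
operational reading of "mostly within 75 km". The altitude range
[0, ceiling] splits evenly into 1–6 strata; cells × strata are volumes.
Per volume, the expected migrant count is the window-mean interpolated
density at the cell centre times the volume (km³). Dividing by the
migrants-per-path count (menu: 10, 25, 50, 100, 250, 500 ×10³) gives the
expected number of pathlines anchored in the volume, apportioned uniformly
over the window's 20-minute steps. Counts are realized as
floor(λ) + Bernoulli(frac λ) — unbiased for any λ, including λ > 1 where a
plain Bernoulli would be undefined — and anchor points are uniform within
the cell footprint to avoid lattice artifacts. The normalization invariant
(E[paths] × migrants-per-path = Σ expected migrants) is verified by Monte
Carlo.

Each anchor integrates with the Heun (two-stage Runge–Kutta) method at
h = ±20 min: with n = duration/step total steps, ⌈n/2⌉ backward then
⌊n/2⌋ forward from the midpoint of the anchor's own time step (for odd n
the extra step goes backward). Each pathline therefore spans one window
length centred near its anchor time, and a window's set of pathlines
tiles the period "around each time step". Velocities at both Heun stages
and densities at each vertex come from the same IDW operator. Where a
stage is unevaluable (field time range exhausted, or no vector-bearing
radar) the pathline truncates and carries a flag; truncated pathlines are
drawn at whatever length they reached.

Drawn curves are cardinal splines through the vertices, tangents
Tᵢ = c·(Pᵢ₊₁ − Pᵢ₋₁)/2 with c the tension (default 0.5; c = 1 is
Catmull–Rom, verified against an independent basis-matrix evaluation;
c = 0 degenerates to the polyline). Line thickness maps the per-vertex
density as t_min + (t_max − t_min)·ρ/ρ_scale clipped to [0.5, 6.0] display
units with ρ_scale = 500 birds km⁻³ — proportional in the useful range and
saturating at extreme densities; all three are style configuration. A dot
marks the temporally last vertex: the direction birds are moving.

## Synthetic cases

The generator emulates the two study networks: a 5-station ~300×300 km
EU-like layout (200-m bins to 4000 m) and a 13-station ~1000×800 km
US-like layout (100-m bins to 3000 m), 5-minute scan cadence. Station
coordinates are synthetic but geographically plausible. Ground-truth
flows: uniform (default 10 m s⁻¹ toward 41° from north — the regional
spring migration axis), solid-body rotation, linear shear, per-band
layered bearings, and a nightly clockwise bearing drift. The density
surface defaults to 150 birds km⁻³ (a moderate migration night), with
optional per-band layering factors, a north–south step ratio, and
per-station factors (used to synthesize quiet, sub-threshold stations).
Noise is zero-mean Gaussian jitter on velocity components (σ_v, m s⁻¹) and
relative jitter on density, clipped at zero; defaults are noise-free so
recovery tests are exact, and σ_v = 0.5 m s⁻¹ / 10 % density jitter are
used as the realistic-noise condition in the tests.

What the generator does not emulate — and hence what passing tests cannot
show about real data: radar beam geometry and range-dependent sampling
volumes, partial dropouts and rain contamination, correlated (rather than
independent) measurement error across altitude bins, and topography. The
pipeline's screening rules are exercised by construction (sub-threshold
layers, clutter bins), not by physical simulation.

## Numerical choices and degenerate inputs

* IDW exact-hit and tie rules as above; relative agreement with the
  brute-force oracle is at machine precision (~1e-15).
* Heun is exact for fields constant in space and time and for the linear
  shear's invariant direction; on rotations its empirical global
  convergence order is ≈2.03 (measured between h = 20 and 5 min).
  Steps of ±20 min at ~10 m s⁻¹ move ≈12 km, well below the ~100 km
  inter-radar spacing the field varies over.
* Zero-length pathlines (zero field) degenerate to endpoint dots;
  single-vertex splines return the point; empty basemaps and empty sample
  sets are legal inputs.
* Problem sizes used in tests and the acceptance script: 4-hour 5-station
  cases (~4560 raw records), 1000-frame streamlet runs, 10 000 Monte-Carlo
  anchor draws — sizes at which every check completes in seconds while
  estimator standard errors remain far below the tested tolerances.

## Known limitations

* The aggregated CSV cannot distinguish a true mean of exactly (0, 0)
  from the zero-velocity convention (see above).
* IDW is a global smoother: it cannot extrapolate gradients beyond the
  sampled hull, and far from all radars every field value tends to the
  k-nearest mean. TIMAMP's 75-km radius keeps the visualization inside
  the region where the reconstruction is meaningful.
* Animation export is GIF (or per-frame PNG); no MP4 encoder is bundled.
* The interactive web controls of the original tools (play/pause, date
  pickers, comment threads) are out of scope; the CLI exposes the same
  selections as flags.
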