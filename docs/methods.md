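# Methods

## The problem

Juvenile Kemp's ridley turtles (*Lepidochelys kempii*) occasionally strand
alive on north-west European coasts in winter, in a hypothermic state.
Below ambient water temperatures of roughly 10-13 °C these ectotherms lose
the ability to swim and float passively ("cold stunning"), after which
their movement is set by surface currents, waves, and wind.  Given a
stranding site and date, this package reconstructs where and when a
stranded individual plausibly entered the cold-stunned state, by tracking
virtual particles backward in time from the stranding and sampling sea
surface temperature (SST) along their paths.

## Drift model

Particles are passive surface drifters advected by the composite leeway
velocity

    v(x, t) = v_curr(x, t) + α · v_wind10(x, t) + v_stokes(x, t)

- `v_curr`: ocean surface currents including tides (m/s),
- `v_stokes`: Stokes drift, the net wave-induced transport (m/s),
- `v_wind10`: wind at 10 m (m/s),
- `α`: the dimensionless *windage factor*, the fraction of the 10 m wind
  felt directly by the floating body.  Literature leeway estimates for
  floating turtles suggest an effective windage of a few tenths of a
  percent to ~1 %; the sensitivity set spans α ∈ {0, 0.001, 0.01, 0.02,
  0.03}.  No leeway divergence angle is applied: windage is a pure scalar
  fraction of the wind vector.

Each forcing field lives on its own regular lon/lat grid with a time axis
and is interpolated independently: bilinear in space on the enclosing cell
(the conventional choice for collocated "A-grid" model output) and linear
in time between the bracketing slices.  Between one and three masked
(land/fill) corner nodes are handled by renormalising the bilinear weights
over the valid nodes, so nearshore sampling is not poisoned by coastal
fill values; a query with all four nodes masked is an error in the scalar
API and substitutes zero velocity inside the vectorised runner (the
anti-beaching rule then disposes of the particle).  Queries outside a
field's time span clamp to the nearest slice with a logged warning — a
120-day backtrack may legitimately out-run a short synthetic record, and a
hard failure would be hostile.

## Integration

Trajectories solve dx/dt = v with classical fourth-order Runge-Kutta at a
10-minute step, backward in time via a negative step (fields are never
negated, so stage-time evaluation remains correct for time-varying
forcing).  Velocities in m/s convert to degrees/s through the local
spherical metric, `(1/(R cos φ), 1/R)·180/π` with R = 6 371 000 m and φ
evaluated at each RK4 stage latitude.  A planar variant with φ frozen at a
reference latitude is available and is used with the solid-body-rotation
test flow: with a fixed metric that flow's velocity field is bilinear,
interpolation is exact, and the analytic circular orbit is a clean oracle
for the integrator's O(dt⁴) convergence.  Under the stage-latitude metric
the same check would be contaminated by an interpolation bias independent
of dt, which is why the two metrics coexist.

No stochastic diffusion is added: the drift of a floating body at the
resolved scales is modelled as purely deterministic, and ensemble spread
comes only from the release scatter.  Runs with equal configuration and
seed are bit-identical.

## Release

10 000 particles per stranding are released in the ocean grid cell
adjacent to the stranding coordinates: by default the ocean cell whose
centre is nearest (great circle) to the site, with ties broken toward the
lower flat index; a config switch (`release_mode="edge-adjacent"`)
restricts the choice to ocean cells sharing an edge with the cell that
contains the site.  Positions are scattered uniformly within the cell from
a seeded generator — co-located releases would be redundant under
deterministic advection.  Reported stranding dates carry no clock time, so
t₀ is 00:00 UTC on the reported date.

## Anti-beaching and terminal states

Discretised coastlines capture particles easily.  After any step that
lands in a land cell the particle is pushed back toward water at 1 m/s
along the shoreline normal — 600 m per 10-minute step.  The normal of a
land cell is the normalised vector sum of unit offsets toward each ocean
cell in its 3×3 neighbourhood; for a straight coast this is exactly the
perpendicular.  A particle is marked *beached* (permanently removed, its
records truncated) when

- its land cell has no usable normal (landlocked neighbourhood or
  cancelling offsets), or
- the push has failed to reach water for `beach_patience = 3` consecutive
  steps (≈ 30 minutes stuck), or
- it leaves the regional domain (recorded as beached-with-reason
  "domain_exit" rather than silently dropped, so ensemble accounting
  always sums to n).

The patience criterion is a concrete, testable reading of "particles that
cannot be freed are marked beached"; the exact count is configurable.

## Cold-stunning events

Positions and interpolated SST are stored daily (including at t₀).  For a
threshold T_c ∈ {10, 12, 14} °C, a particle's *cold-stunning event* is the
most recent downward crossing before stranding: the latest forward-time
record strictly below T_c whose predecessor is at or above T_c.  The
strict/non-strict split pins the convention that an exact-threshold record
counts as "not yet stunned".  Series that never dip below T_c yield no
event, and so do series below T_c at every record — such particles never
crossed inside the window (e.g. arrivals from already-cold water) and are
excluded from the statistics.  Detection operates on the stored daily
records, not on internal 10-minute steps, so event times are resolved to
1 day.  Beached particles are scanned over their pre-beaching records
only; a crossing found there still counts.

Each event carries its time before stranding (days), location, and
great-circle distance from the stranding site (haversine, R = 6371 km).
The distance is point-to-site, not along-trajectory.

## Aggregation

Summaries are keyed by (stranding or pooled, windage α, T_c) and report
crossing counts and fractions, beached fractions, and the mean and
(0.05, 0.25, 0.5, 0.75, 0.95) quantiles of event days and distances.
Two pinned conventions:

- the denominator of `frac_crossed` is **all released particles** in the
  group, beached included (five production releases pool to n = 50 000);
- quantiles interpolate linearly between order statistics (type 7).

Pooled moments are event-weighted (each event counts once; strandings are
not re-weighted), and per-stranding tables can always be emitted
alongside.  Rows for configured thresholds with no events anywhere are
emitted with `has_events = False` and NaN moments rather than dropped.

## Synthetic forcing (what the generators emulate, and what they don't)

Real runs are forced by shelf-sea reanalysis currents/SST (~7 km, daily),
a wave-model Stokes drift (~1.5 km, 3-hourly) and 0.25° reanalysis winds —
external archives.  The `synthetic_ocean` generators replace them with
analytically tractable stand-ins of the winter southern North Sea:

- **uniform flow** — closed-form displacement;
- **solid-body rotation** — circular-orbit oracle for integrator order;
- **shelf sea / tidal channel** — mean drift (default 0.1 m/s) plus a
  sinusoidal tidal oscillation (default amplitude 0.5 m/s, period
  44 712 s: the dominant M2 constituent, hourly slices so linear time
  interpolation resolves it), constant south-westerly wind (8, 4) m/s and
  Stokes drift (0.02, 0.01) m/s, and a half-plane or channel coastline;
- **cooling SST front** — SST(x, t) = T_off + g·(x − x_coast) − c·t_days,
  linear in space and time, hence interpolated exactly, with a closed-form
  threshold-crossing time.  Defaults (T_off = 14 °C, c = 0.05 °C/day over
  120 days) sweep the field through the 10-14 °C cold-stunning band down
  to the ~8 °C regional winter minimum.

Synthetic wind and Stokes drift are spatially uniform by default, which
isolates windage effects and makes the windage-linearity check exact.
The generators do *not* emulate realistic bathymetry, mesoscale
variability, data-assimilative spectra, or convoluted coastlines; a green
test on them establishes the correctness of the numerics and the event
logic, not the realism of any particular hindcast.  The five packaged
stranding records (sites and dates, 2007-2021) are real fixture data.

## Numerical choices and edge cases

- Composite velocity is summed as `(currents + α·wind) + stokes`, and
  bilinear/time interpolation uses the difference form
  (`c00 + fx·(c10 − c00)`, …), so constant fields interpolate to exactly
  the constant and merging `α·wind` into the currents field is
  bit-for-bit equivalent to applying windage at run time on uniform
  fields.
- Point-in-cell uses half-open cells ([west, east) × [south, north)); a
  point on a shared edge belongs to the greater-index cell, so every
  point maps to exactly one cell.
- Longitudes are plain Cartesian coordinates on a regional domain
  declared on [-180, 180); no wraparound.
- Spatially-uniform time slices are detected at field construction and
  served through a fast path (the synthetic default forcing is uniform in
  space), which keeps 10⁴-particle ensembles at interactive speed.

## Known limitations

- Forward prediction, active swimming above the threshold, vertical
  motion, and physiological onset modelling are out of scope.
- Only regular lon/lat A-grids are supported (no curvilinear or staggered
  grids, no cubic interpolation).
- Event times inherit the daily output resolution; sub-daily crossing
  interpolation is deliberately not attempted.
- Single-process determinism is the contract; there is no parallel
  execution path.
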