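# Methods

This note documents the models behind `dropmix`, the defaults and their
units, the numerical choices, and the limits of what the synthetic tests
demonstrate.

## Residence-time model

A device is three ordered channel sections. Section `A` (the Y-mixer)
carries only the combined aqueous flow `Q_aq = Q_X + Q_S`; sections `B`
(droplet former) and `C` (exit capillary and nozzle path) carry the total
flow `Q_T = Q_aq + Q_O`. Each residence time is `t = L / (Q/area)` with
the slug in the capillary assumed to travel at the section mean velocity.
Gas-phase acceleration inside the nozzle is excluded from `t_R`, matching
how the probed time point is defined for these devices.

Preset geometries: DG300-Y has 150 × 150 µm channels throughout; DG250-Y
has a 100 × 100 µm aqueous mixing channel joining a 150 × 150 µm droplet
channel. Section `C` is a 100 µm inner-diameter fused-silica capillary.
Its drawn length is quoted as 15.4 mm, a value rounded to three figures;
the presets use an effective hydraulic length of **15.42 mm**, the single
length within that rounding that reproduces the published residence times
of *both* device variants at their reporting precision (15.40 mm gives
0.258 s instead of 0.259 s for the DG250 capillary time). Residence
components are reported at 3 decimals and `t_R` at 1 decimal.

Units at the interface are µL/min, µm and seconds; conversion happens at
the boundary (1 µL/min = 1e9/60 µm³/s).

## Mixing transport model

Transport of substrate across the co-flowing streams in section `A` is
modelled single-phase and two-dimensional. With axial Péclet number
`Pe = v̄ w / D` large (≈ 800 for DG300 run conditions), axial diffusion is
negligible and the steady problem parabolizes to

    u(y) ∂c/∂x = D ∂²c/∂y²,   u(y) = 6 v̄ (y/w)(1 − y/w),

marched downstream from a step inlet profile. The interface position `y*`
follows from the flow split: the cumulative parabolic-profile flow
`3r² − 2r³` (r = y/w) between the crystal-side wall and `y*` equals
`Q_X/Q_aq`. The solver refuses to run below `Pe = 50` and names the
neglected term. The plane-Poiseuille profile is used rather than the full
rectangular-duct series; for square ducts this overestimates the velocity
at the 20 µm offset line by under 10%, which is small against the
two-phase effects discussed below.

The substrate diffusivity is viscosity-corrected with the Einstein
relation `D = D_ref η_ref / η`. Defaults: NADH `D_ref = 6.7e-6 cm²/s` in
water (`η_ref = 1.00 mPa·s`, room temperature) and mother-liquor viscosity
`η = 5.39 mPa·s` (18% PEG 3350), giving `D = 1.24e-6 cm²/s`.

**Equimolarity criterion.** Mixing at a point is considered complete when
the substrate concentration equals the protein concentration inside the
crystal — 23 mM for NQO1 crystals, an input parameter with that default
(its crystallographic derivation is out of scope). Because ~20 µm crystals
cannot approach the wall closer than about one crystal radius, the
criterion is evaluated on an offset line `y_offset = 20 µm` from the
crystal-side wall. The inlet substrate concentration default is 300 mM.

**Spread of reaction initiation.** Over the distance `L` from the stream
junction to the equimolarity point, fluid at mid-channel moves at
`1.5 v̄` and fluid on the offset line at `u(20 µm) ≈ 0.69 v̄`; the
transit-time difference `Δt_m = L/u(y_offset) − L/u(w/2)` is the
streamline spread of initiation times. Adding the substrate diffusion
time into the crystal interior (default 15 ms for a 10 × 20 × 30 µm³
crystal) gives the total spread and its fraction of `t_R` — e.g. the
published 5.6 ms streamline spread for the DG250 geometry plus 15 ms of
crystal-interior diffusion is ≈ 21 ms, 7% of the 0.3 s time point. (The
5.6 ms value itself is not derivable from a straight centre-versus-offset
computation over the full mixer length; it is treated as an input, not a
model output.)

**Single-phase limitation.** Two-phase simulations of these devices show
a concentration drift toward the crystal-side corner as the droplet
pinches off, which carries substrate across streamlines far faster than
transverse diffusion alone. That mechanism places the equimolarity point
inside section A for DG300 run conditions. The single-phase model here
cannot reproduce it: at `Q_X/Q_S = 0.5/0.4 µL/min` the 61 µm gap between
the inlet interface (y* ≈ 81 µm) and the 20 µm offset line needs ~7 s of
diffusion at 120 µm²/s while only ~1.1 s is available, so the computed
offset-line concentration at the end of the mixer is ~3e-4 mM and
`equimolar_distance` correctly reports "not reached". Consequently the
associated acceptance test fails by design of the model scope, and the
reported two-phase transit times (0.161/0.363 s) are compared only through
their velocity *ratio* 2.25, which the parabolic profile reproduces as
`u(w/2)/u(20 µm) = 2.16` (4% apart). Slower-flow configurations (e.g.
0.05/0.04 µL/min, Pe ≈ 80) do reach equimolarity in-domain and are used to
test grid convergence and monotonicity.

**Numerics.** Backward-Euler marching with a tridiagonal solve per step is
unconditionally stable and positivity-preserving (the diffusion matrix is
an M-matrix), keeps `c ∈ [0, c0]`, and conserves the discrete advective
flux exactly (the zero-flux wall rows telescope the diffusion stencil).
Default grid: 512 axial steps × 257 transverse nodes over 528 × 150 µm.
Validation at this scale: plug-flow output vs the closed-form erfc
similarity solution agrees to 0.48% RMS of `c0`; flux conservation is at
machine precision; the equimolar distance changes by 0.5% when both grid
spacings are halved.

## Pulse-train and droplet-volume criteria

Train duration is counted as `n_pulses × spacing` (202 × 1.77 µs =
357.5 µs ≈ 358 µs), not `(n−1) × spacing`; the difference is below the
quoted rounding. During jetting the droplet is approximated as a rod of
the jet radius (default 5 µm, jets being 3–10 µm in diameter) moving at
the jet velocity (default 25 m/s), with no end-cap correction; the
minimum train-spanning volume is `π r² v T ≈ 700 pL`. Note that the rod
length itself is `v·T = 8.94 mm` — a quoted travel distance of 5 mm for
the same parameters is inconsistent with the 700 pL figure and is not
used. Flow-balance droplet volume is `Q_aq / f` (2.5 nL at 1.5 µL/min and
10 Hz, compatible with measured volumes of ~2.3 nL).

## Synchronisation simulator

The generator is an integrate-and-fire oscillator: inter-droplet periods
are `1/f₀` with Gaussian jitter (`period_jitter_sd`, default 0) and an
optional slow fractional drift. Each reference tick (10 Hz, 100 ms
period) emits a trigger at a fixed `delay` (default 30 ms) lasting
`duration` (default 4 ms). The electrode actuation is abstracted as
*phase-resetting capture*: if the oscillator is within `capture_width`
(default 20 ms) of firing while a trigger is active, the firing is
re-timed to the trigger, zeroing the phase error. Amplitude at or above
`lock_threshold` (default 150 V) captures deterministically; a fraction
`amplitude/threshold` of triggers capture below it; amplitude 0 leaves the
oscillator free-running. This is a behavioural model of the observed
amplitude ladder (180 V locks immediately, 110 V locks intermittently,
40 V fails to hold lock), not an electro-hydrodynamic one; the threshold
and capture width are chosen so the ladder's qualitative ordering is
reproduced. A single integer seed drives all draws; identical seeds give
identical event trains.

Diagnostics: detector traces are synthesised as rectangular pulses
(default 2 ms wide, 10 kHz sampling) plus Gaussian noise and analysed by
rising-edge threshold detection with a refractory hold-off of one pulse
width (two pulses closer than the hold-off merge into one event).
Waterfall matrices stack consecutive reference windows; only whole
windows are kept and every event within them is preserved. The per-window
phase is the *first* droplet in the window; phases are summarised on the
unit circle (circular SD `sqrt(−2 ln R)`, mapped back to seconds) so a
locked train straddling the window boundary is still read as tight. A
window counts as locked when the rolling circular SD over the trailing 5
fully-occupied windows is below 1 ms. The free-running fixture detunes
the oscillator to 10.15–10.2 Hz with 2 ms jitter so an unlocked generator
visibly walks in phase (≈1.5–2 ms per window) rather than mimicking lock
by accident; a generator within ~0.05 Hz of the reference would drift
slowly enough to defeat any finite-window lock metric.

Hit records are Bernoulli draws restricted to windows whose droplet phase
is within a tolerance (default 2 ms) of the trigger delay, reflecting that
only droplets coincident with the train can produce crystal hits. The hit
rate is defined per pulse: `n_patterns / (n_trains × pulses_per_train)`
(1631 patterns over 2018 trains of 202 pulses ≈ 0.40%).

## Sample accounting

"Sample injected" is the crystal-stream volume `Q_X × time` only; the
substrate stream is accounted separately. The continuous-injection
comparator is a jet at the *same total flow rate for the same duration*,
which makes the savings `1 − Q_X/Q_T` independent of duration and
concentration; equal-pattern-count comparisons can be formed from the
patterns/µL figures but are not the headline metric. Patterns/µL are
rounded to integers and masses to 1 decimal for reporting; exact ratios
are retained internally. Computed masses follow strictly from the inputs:
186.2 µL × 18 mg/mL = 3.35 mg for the 0.3 s run and 42.75 µL × 25.5 mg/mL
= 1.09 mg for the 1.2 s run; published per-run consumption figures that
mix additional runs or rounding (3.2 mg, 1.7 mg, ">60 mg" continuous) are
not reconstructed from these inputs alone.

## What the synthetic tests do and do not show

All tests run on generated fixtures or printed run parameters; nothing is
downloaded. The simulator fixtures emulate the qualitative beamline
regimes (locked, free-running, intermittent, amplitude ladder) with clean
rectangular detector pulses and stationary noise — they do not emulate
real detector baselines, double droplets, satellite droplets, or slow
hardware drifts, so passing lock-in tests demonstrate the correctness of
the metrics and the behavioural capture model, not hardware performance.
Likewise the mixing tests validate the single-phase solver against its
own closed-form limit; they deliberately do not claim to reproduce
two-phase droplet-formation fields. Simulation sizes (60 s lock-in runs,
512 × 257 mixing grids) are chosen as desk-scale defaults that leave all
validation metrics comfortably inside their tolerances.
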