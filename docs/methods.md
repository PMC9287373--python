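# Methods

This note documents the models, parameter choices, and numerical conventions
behind `ferrynoise`, and what the synthetic validation does and does not
demonstrate about real data.

## Environment and transmission loss

The site is modeled as an isovelocity water layer of height h = 8 m
(receiver-side value; the hydrophone sits 2 m above the seabed, so at 6 m
depth) over a homogeneous fluid half-space. Water sound speed defaults to
c_w = 1500 m/s and the seabed to c_b = 1.06·c_w. The harbor literature for
clay/silt/sand bottoms supports ratios of 1.04–1.06; the upper value with
h = 8 m places the modal cutoff

    f0 = c_w / (4 h sqrt(1 − (c_w/c_b)²)) = 141.3 Hz

exactly at the analysis band's lower edge, which is why it is the default.
Both speeds, the densities (1000 / 1700 kg/m³), and the seabed attenuation
are config-exposed.

Transmission loss comes from pluggable engines used identically in the
forward (synthesis) and inverse (backpropagation) directions:

- **Pekeris engine (default).** Trapped modes solve
  ρ_b γ cos(γh) + ρ_w β sin(γh) = 0 with β = sqrt(γ_max² − γ²), one root per
  interval ((n−½)π/h, min(nπ/h, γ_max)), found by Brent's method after
  analytic bracketing. Levels use the incoherent mode sum
  Σ ψ_n²(z_s) ψ_n²(z_r) e^(−2α_n r) / (k_n r), appropriate for band- and
  minute-averaged levels (a coherent sum is available behind a flag). The
  sum is referenced to its own 1-m value, so TL(1 m) = 0 and source levels
  are dB re 1 µPa·m by construction; mode shapes vanish at the pressure-release
  surface, so the Lloyd's-mirror image interference is internal to the
  engine rather than a separate correction. A full range-dependent
  parabolic-equation solve is deliberately out of scope: the analysis rests
  on *relative* levels under a consistent engine, and the receiver-side
  depth dominates the modal structure at these ranges. The bathymetry
  profile (100-m grid) is used for range sampling and diagnostics only.
- **Practical-spreading engine** k·log10(r) + α·r/1000 (k ∈ [10, 20],
  default 15) as a fallback for degraded configurations.

Seabed attenuation defaults to 0 dB/wavelength (lossless half-space). When
nonzero it enters as a first-order perturbation of the bottom loss tangent,
attenuating each mode in proportion to its energy fraction in the bottom.
With the lossless default the far field is purely cylindrical
(10 dB/decade), which the tests assert between 2 and 20 km.

Below f0 no trapped mode exists. Rather than failing, the engine returns
the practical-spreading loss plus an evanescent penalty of 10 dB per 100 m
beyond 100 m (config-exposed). The analysis band never enters this regime;
the rule only keeps out-of-band queries well-defined and strongly
suppressed.

## Bands and dB conventions

Seven decidecade (one-third-octave, base-10) bands span 10^2.15–10^2.85 Hz;
141 and 707 Hz are standard decidecade edges and the bracketed nominal
centers are 160–630 Hz. All operations are grid-agnostic; the grid is
config-exposed. Sub-minute levels are power-averaged into 1-min blocks
(10·log10 of mean intensity); broadband integration is the dB sum over
bands. Received levels are dB re 1 µPa, source levels dB re 1 µPa·m. No
ambient subtraction is performed at backpropagation; the synthetic module
quantifies ambient contamination instead (see below).

## Kinematics and event definitions

AIS records are bucketed to a regular 1-min grid (nearest minute; duplicate
records averaged, with a circular mean for COG). Distances use the haversine
formula with the WGS84 mean radius (6371.0088 km); at ≤ 20-km ranges the
error is far below the 100-m bathymetry resolution. STW subtracts the
nearest-in-time hourly current vector from the AIS ground-velocity vector;
both bearings are "toward" directions in degrees true — stated explicitly
because current-vector sign conventions vary between providers.

STW is smoothed with a centered 3-min boxcar (edge-renormalized), absorbing
clock desynchronization between the AIS feed and the recorder, then
differentiated by central differences (one-sided and flagged at the track
ends); jerk applies the same scheme to acceleration.

Events:

- **t_CPA**: the sample minimizing distance (earliest on ties).
- **t_acc**: inside the phase of interest — launching for outgoing transits,
  docking for incoming ones — the two highest-prominence peaks of the
  (negated, for deceleration) acceleration form the double-peak signature of
  the two engine-regime steps; t_acc is the trough between them, i.e. the
  jerk-sign-change instant. Peak prominence floor 0.3 kn/min and minimum
  separation 2 min; transits without two qualifying peaks are excluded with
  a reason code. The peak search spans from the track edge to t_CPA (or from
  t_CPA to the opposite edge) rather than stopping at the motion-threshold
  bounds: a boundary placed on a pulse flank would clip that peak's
  prominence.
- **Phase windows**: acceleration kickoff is the first minute smoothed STW
  rises through 1 kn, deceleration end the last minute above it. The window
  of interest is [kickoff, t_CPA] outgoing and [t_CPA, decel end] incoming.
  Mid-transit AIS gaps > 5 min flag the transit unusable.

## Statistics

Per-transit rows carry (d, STW, a, BB_MSL) at t_CPA and t_acc plus a
scheduled time-of-day slot (three departures, three arrivals; nearest slot).
Design choices, in the package's own words:

- dB values are averaged **arithmetically** in mode means and ΔBB — matching
  the "mean ± 1σ dB" reporting convention — not power-averaged.
- ΔBB normal fits are maximum-likelihood: sample mean and population (1/n)
  σ. Only transits with both modes measured contribute.
- The KS statistic D is the sup ECDF distance (scipy's two-sample statistic);
  no p-value by default.
- The mixed model is Gaussian with fixed effects d (in **km** — coefficient
  magnitudes are implausible per metre), STW (kn), a (kn/min), and a random
  intercept per time-of-day slot, fitted by REML with Wald 95% CIs and
  p-values. Singular fits (vanishing slot variance) are returned flagged,
  not raised. No multiple-testing correction is applied, and no AIC model
  scan is performed — only the single reported model per (mode × direction).

## Synthetic scenarios

The generator emulates the study conditions: six scheduled trips per day
(departures 08:00/12:00/16:00, arrivals ≈ 11:00/15:00/19:00 EDT, start
delays of a few minutes), straight-line routes past the hydrophone with CPA
distances of 350–450 m and the dock ~2.6 km along-route, transits of
75 ± 8 min with 7–9.5-min speed-change phases (≈ 20% of transit time in
speed change across a batch), plateau speed 12.8 kn, M2-tidal (12.42-h)
currents and ambient modulation (quiet at slack water, base 88 dB per band,
3-dB tidal excursion, 1-dB jitter), and double-peak acceleration profiles
built from two Gaussian pulses ~4–5 min apart with distinct amplitudes. The
acceleration pulses integrate exactly to the plateau speed. AIS is sampled
at 1 min with ground velocity = water velocity + current, so the kinematics
chain inverts it exactly.

Ship source levels are injected per 1-min block: the speed-change level
inside the acceleration/deceleration windows, and the design-mode level plus
slope·(STW − V_op) elsewhere. Synthesis and backpropagation share the block
timestamps and AIS-derived distances, making the forward→inverse round trip
an exact identity when ambient is disabled and the engines match — the tests
assert recovery to ≤ 1e-9 dB, so all downstream error is attributable to
ambient noise and event-detection timing, not plumbing. With the default
ambient on, contamination biases extracted broadband levels by ≲ 0.01 dB at
these ranges.

**Calibrated preset.** The preset encodes reported study statistics as
ground truth: per-direction CPA broadband means (172.07 / 170.42 dB,
σ 3.42 / 3.27), speed-change means (182.14 / 183.34 dB), paired ΔBB normal
fits (8.04 ± 5.02 / 11.50 ± 4.67 dB), CPA speed slopes (1.41 / 1.49 dB/kn),
and the implied aspect offsets (port−starboard ≈ 1.65 dB at CPA,
stern ≈ 1.2 dB while docking). Two deliberate mechanisms:

- **Batch moment matching.** Per-transit draws (transit effects, slot
  offsets, plateau-speed jitter, mode offsets) are standardized so each
  batch's empirical mean and σ equal the target values exactly. The preset
  thereby *encodes* the reported fits rather than sampling around them;
  recovery tests measure pipeline error, not Monte-Carlo shot noise.
- **Pairing structure.** The reported ΔBB centers are smaller than the
  differences of the reported per-mode means, which is only possible if the
  usable-transit sets differ between modes. The preset reproduces this: a
  fraction (0.3) of transits lose their hydrophone blocks around CPA
  (recording dropouts) and contribute only their speed-change half, and
  those unpaired transits carry a larger mode offset solved in closed form
  so that the full-set per-mode means and the paired ΔBB fit are both on
  target simultaneously. Per-transit variance splits 80% transit / 20%
  time-of-day slot — a documented choice, not a reported decomposition —
  giving the mixed model a true random-intercept variance.

One consequence worth stating: with these per-mode distributions the
population KS distance between CPA and speed-change levels is ≈ 0.71 for
outgoing trips and ≈ 0.85 for incoming — "fairly close to 1" holds more
strongly for incoming transits, and no variance split can raise the outgoing
value while keeping the encoded means and σs.

## What passing tests show — and what they do not

The synthetic campaign validates the estimation chain end to end under known
truth: geometry, modal propagation with a matched engine, event detection at
1-min sampling (≥ 95% double-peak detection across seeds), and the
statistics. It does **not** exercise: raw-waveform processing and hydrophone
calibration (the pipeline ingests calibrated band SPL series; the
−175.7 dB re 1V/µPa sensitivity is fixture metadata only), range-dependent
propagation over real bathymetry, spatially varying currents, wind/sea-state
noise, multi-vessel scenes, or flow pseudo-noise at the sensor. Absolute MSL
accuracy on real data therefore remains limited by the environment model;
the mode-to-mode *relative* comparisons are the robust product, as they are
for the field analysis.

## Numerical details and degenerate inputs

- Mode roots: Brent to |Δγ| ≤ 1e-14; dispersion-relation brackets are
  analytic, so no root is missed; mode count grows as ⌈f/(2f0) + ½⌉.
- Problem sizes: validation batches use 100 transits per direction (the
  study's scale) for recovery checks and 3–24 transits for identities and
  examples; the mixed-model recovery uses 90 observations and 20 seeds.
- Ties: CPA ties break to the earliest sample; broadband extraction at a
  timestamp equidistant between blocks takes the earlier block and fails
  beyond 1 min.
- Extraction at a minute grid means detected-event timing errors of ±1 min
  map to block choice, not interpolation; during speed-change phases the
  injected level is phase-constant, so timing error does not bias recovery.
- Empty tracks, all-missing distances, stationary tracks, sub-minimum
  sample counts, and ranges below 1 m raise typed errors
  (`ferrynoise.errors`); transits excluded by the pipeline always carry a
  logged reason.

## Known limitations

- The Pekeris engine is range-independent by design; sloping bathymetry
  enters only through diagnostics.
- The incoherent sum underestimates interference nulls at short range; this
  is intentional for 1-min/band-averaged levels.
- With only three slots per direction, the random-intercept variance is
  weakly identified; singular fits are expected on small batches and are
  flagged rather than hidden.
- The generator's flat source spectrum across the seven bands is a
  simplification (only broadband levels are calibrated); a sloped variant
  exists behind a flag but is not calibrated.
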