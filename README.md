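# ferrynoise

Underwater radiated noise of a harbor ferry, estimated per operating mode
from AIS tracks and hydrophone band spectra.

Ferries spend a large share of every transit launching and docking. During
those full-throttle acceleration and reverse-thrust deceleration phases a
ship can radiate an order of magnitude more low-frequency noise than at its
design speed — which matters in shallow coastal habitats used by
noise-sensitive marine mammals such as the St. Lawrence Estuary beluga.
`ferrynoise` is a tested re-implementation of that analysis chain for
researchers in marine bioacoustics and conservation ecoacoustics: it turns
vessel kinematics and received hydrophone levels into **monopole source
levels (MSLs)** for two operating modes — speed-change events near the dock
and passages at quasi-operational speed at the hydrophone's closest point of
approach (CPA) — and compares them statistically.

## Model

Working in one-third-octave (decidecade) bands on [f₀, f₁] = [141, 707] Hz:

- **Waveguide cutoff.** A shallow channel is a high-pass filter; the lowest
  propagating frequency is
  `f₀ = c_w / (4 h √(1 − (c_w/c_b)²))`,
  which for h = 8 m and a seabed/water sound-speed ratio of 1.06 gives the
  141-Hz lower band edge.
- **Backpropagation** (passive SONAR equation, per band and 1-min block):
  `SL(f, t) = RL(f, t) + TL(f, d(t))`,
  with TL from a pluggable engine — by default an incoherent sum over the
  trapped normal modes of a Pekeris waveguide (isovelocity water over a
  faster fluid half-space), referenced so TL(1 m) = 0; MSLs are
  dB re 1 µPa·m and include the sea-surface (Lloyd's mirror) image by
  construction.
- **Broadband integration:** `BB(t) = 10·log₁₀ Σ_bands 10^(L(f,t)/10)`.
- **Kinematics.** Speed-through-water STW = |v_ground − v_current| from
  AIS SOG/COG and surface-current predictions; 3-min boxcar smoothing;
  acceleration and jerk by finite differences. The speed-change event time
  t_acc is the jerk-sign-change instant between the two peaks of the
  double-peak acceleration signature; t_CPA minimizes the ship–hydrophone
  distance.
- **Statistics.** Per-transit ΔBB ≡ BB_MSL^acc − BB_MSL^CPA with normal
  fits, per-mode means ± 1σ, two-sample Kolmogorov–Smirnov D, and the
  Gaussian linear mixed model
  `BB ~ d + STW + a + (1 | time-of-day slot)` (REML, Wald inference),
  which yields the dB-per-knot speed dependence at CPA.

Because the original recordings are not public, a first-class synthetic
scenario generator stands in for the field campaign: it emulates the transit
schedule, double-peak speed profiles, tidally modulated ambient noise, and a
*calibrated preset* whose injected per-mode broadband truths equal the
study's reported statistics, so the full pipeline can be validated against
known ground truth.

## Worked example

```sh
ferrynoise generate --out scen --seed 13 --n-outgoing 12 --n-incoming 12 --preset paper
ferrynoise analyze --scenario scen --out out --seed 13
ferrynoise report --out out
```

prints (abridged):

```
Ferry broadband monopole source levels, per operating mode
transits analyzed: 24 (excluded: 0)

BB_MSL CPA  incoming : 170.26 +- 3.92 dB (n=8)
BB_MSL CPA  outgoing : 172.16 +- 3.53 dB (n=8)
BB_MSL ACC  incoming : 183.50 +- 7.41 dB (n=12)
BB_MSL ACC  outgoing : 182.37 +- 8.09 dB (n=12)
BB_MSL CPA  pooled   : 171.21 +- 3.73 dB (n=16)
BB_MSL ACC  pooled   : 182.93 +- 7.61 dB (n=24)

DeltaBB incoming: 11.50 +- 4.67 dB (n=8)
DeltaBB outgoing: 8.04 +- 5.02 dB (n=8)
KS D incoming: 0.833
KS D outgoing: 0.792
```

Reading: on this 24-transit synthetic campaign the ferry's broadband MSL
during speed changes exceeds its CPA level by ~8 dB (outgoing) to ~11.5 dB
(incoming) — the ship is roughly an order of magnitude noisier while
launching or docking — and the KS statistic near 1 shows the two operating
modes are statistically distinct. Some transits lose their CPA block to
simulated recording dropouts and contribute only their speed-change half
(n=8 vs n=12 above), mirroring how unequal usable-transit sets arise in a
real campaign.

The library mirrors the CLI: `generate_scenario`, `analyze`, and the
per-module functions (`cutoff_frequency`, `pekeris_tl`, `backpropagate`,
`broadband`, `phase_windows`, `fit_mixed_model`, …) are importable from
`ferrynoise`.

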