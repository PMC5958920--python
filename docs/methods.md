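# Methods notes

This note records the models, conventions and numerical choices behind
`mechanops`, in the spirit of a model-documentation page: what is assumed,
what the defaults mean, and what the tests do and do not demonstrate.

## Units and conventions

Lengths are in μm, sub-pulse durations in ms, trace time axes in s, speeds
in μm ms⁻¹, pressures in kPa, and currents are normalized to a unit
baseline (I = 1). All the headline quantities (blockade fractions, wCDI,
δ_deform, ε) are ratios, so normalization removes amplifier gain without
loss. File readers convert at the boundary; config values may carry unit
suffixes ("2.055 mm", "100 kHz"). Sample indexing is 0-based and event
times are seconds from trace start.

## Sizing model

The Coulter blockade relation ΔI/I = d³/(D_e²L)·[1 − 0.8(d/D_e)³]⁻¹ is
strictly increasing in d up to the pole at d = D_e·0.8^(−1/3) ≈ 1.077 D_e.
Both inversions (cell diameter given ΔI_np/I; effective diameter D_e given
microsphere blockades) use bracketed Brent root-finding on this monotone
branch with ≤1e-9 relative residual; calibration additionally enforces the
physical constraint D_e > d_sphere and reports per-sphere relative
residuals. L is the sensed channel length, taken as the sum of the segment
lengths of the configured layout.

The contraction blockade is converted to occluded volume with a
proportionality constant of 1 (ΔI_c/I = V_deform/V_contraction). The true
constant is device-specific and of order one; it is exposed as
`occlusion_scale` for empirical calibration. The oblate-spheroid relation
V = π w_c L_deform²/6 then yields the elongation.

## wCDI and π-terms

wCDI = [L_c/(U_flow·h_channel)]·[D_cell/ΔT_cont]. U_flow is estimated
per cell as the speed through the last pre-contraction pore (pore length
over sub-pulse duration), a proxy for the node-section fluid velocity; a
per-run override is possible by constructing `FlowContext` directly. The
π-terms are π₂ = h/(ΔT_cont·U_flow), π₃ = D_cell/h, π₄ = L_c/h, chosen so
that π₂·π₃·π₄ ≡ wCDI exactly (this identity is the binding convention;
with time in the numerator instead, the product would not reduce to the
index). π₁ = h·E/(U_flow·μ) is reported only when the elastic modulus and
viscosity are supplied, with U_flow converted to μm s⁻¹ so the group is
dimensionless. No analytic wCDI↔E mapping is provided: only the inverse
empirical relation is established, so any such map would be speculative.

## Device defaults and the recovery window

The default layout is 3 pore/node pairs, one contraction channel
(L_c = 2055 μm, w_c = 12 μm, h = 30 μm), and 7 node/pore pairs after it;
pores are 100 μm long and 25 μm wide, nodes 85 μm square. Recovery is
only observable while the cell is still inside the post-contraction
node-pore sequence, so the package's default classification window is the
*geometry-derived observable window*: the elapsed time from the
contraction exit to the midpoint of the last post-contraction pore
(≈ 24.9 ms at the default 50 μm ms⁻¹ node speed). A fixed window (for
example the 40 ms of a longer post sequence) can be passed explicitly;
recovery times beyond the observable span are censored and classified
prolonged either way. The boundary case ΔT_r = window is transient.

## Pulse extraction

- **Filtering**: zero-phase 4th-order Bessel low-pass (magnitude-normalized,
  forward–backward). A Bessel response is used because plateau amplitude is
  the measurand: its step response has negligible overshoot, whereas a
  Butterworth of the same order rings by ~10% of the step, which on the deep
  contraction edges is comparable to a small cell's pore amplitude.
- **Baseline**: rolling median of 10 ms block medians over a 1 s span,
  interpolated to the full time base. The span must greatly exceed an event
  duration (~70 ms at defaults); it tracks linear drift and interpolates
  under events.
- **Detection**: hysteresis thresholding of baseline − current, entering at
  k·σ (k = 5) and extending to k·σ/2, where σ is a MAD-based robust noise
  estimate with two floors: an absolute 1e-9 and a minimum resolvable depth
  of 1e-4 normalized units (so noise-free traces do not threshold on
  residual filter transients). Runs separated by less than 10 ms (node
  returns to baseline) merge into one event window.
- **Coincidence**: a window is rejected when (a) it contains more sub-pulse
  runs than the geometry predicts, (b) it contains more than one run much
  longer than the median run (two contractions), or (c) a plateau's
  interior 5–95% spread exceeds 30% of its amplitude plus a noise
  allowance — superposed cells leave internal steps inside plateaus that a
  single cell cannot produce. Composite pulses are counted and excluded,
  not deconvolved.
- **Amplitudes** are baseline minus the trimmed-interior median of each
  plateau (trim = 2 samples-per-cutoff-period, discarding filter edges);
  **edges** are half-amplitude crossings interpolated between samples.
  ΔI_np averages all pre-contraction pores (a dialect choice; the first
  pore alone is equally defensible).
- **Recovery time**: the clock starts at the contraction exit edge. ΔT_r is
  the time to the midpoint of the first post pore whose amplitude is within
  the equality tolerance (default 5%, configurable) of ΔI_np, linearly
  interpolated between successive post-pore midpoints when the crossing
  falls between them; first-pore pass ⇒ instant (ΔT_r = 0); no pass
  in-window ⇒ censored/prolonged. ΔT_r is therefore quantized at the
  pore-pair spacing (~3.7 ms at defaults), which bounds its accuracy.

## Synthetic-data generator

The simulator is first-class: it renders the canonical pulse anatomy with
per-cell ground truth so the extraction chain can be validated end to end.
Defaults describe a realistic epithelial screen: diameters N(16, 2²) μm
truncated to the channel's feasible range; node-section speed 50 μm ms⁻¹;
ΔT_cont = slowdown · (L_c/speed) · (D_cell/16 μm) with the slowdown factor
lognormal (median 0.73, log-sd 0.2), giving ~30 ms transits at the
reference size; recovery mix 50/30/20 instant/transient/prolonged;
transient recovery times uniform on 6–20 ms (inside the observable
window, clear of both the first post-pore midpoint and the censoring
boundary); white noise sd 6.5e-5 (amplitude SNR ≈ 20 for a 16 μm cell) and
zero drift unless configured. The linear size-scaling of ΔT_cont encodes
the observation that larger cells transit the contraction more slowly and
is exactly the effect wCDI is designed to cancel; simulated populations
differing only in mean diameter produce statistically indistinguishable
wCDI means.

Transient recovery follows a single-exponential amplitude-deficit decay
with initial deficit 0.30 of ΔI_np, the time constant chosen so the
deficit reaches the analysis tolerance exactly at the drawn ΔT_r;
prolonged cells hold a constant 0.15 deficit. Only the endpoint criterion
is empirically constrained; the exponential trajectory is a modeling
choice. Edges are rendered by area sampling (each sample holds the mean
level over its sample interval) and event starts snap to the sample grid,
so noise-free edge positions round-trip to well under one sample. Not
emulated: 1/f noise, RC electrode dynamics, off-axis particle corrections,
pressure-driven velocity profiles, partial-overlap waveform physics
(overlaps superpose linearly). Passing round-trip tests therefore
demonstrates correctness of the analysis chain under the stated pulse
anatomy, not robustness to every artifact of a physical recording.

## Population statistics

- **Summaries** remove wCDI outliers beyond 3 sd of the mean in a single
  pass (not iteratively), then report mean/sd of wCDI, mean strain and
  recovery-type proportions.
- **Overlap coefficient**: ∫min(f₁,f₂) computed from the ≤2 roots of the
  log-density quadratic plus normal CDF tails, with interval membership
  decided on log densities (linear-space pdfs underflow in far tails).
  A brute-force grid integration is kept as the test oracle. From the
  *printed, rounded* population parameters the analytic overlaps are 2.43%
  and 28.11% for the two published comparisons versus 2.6% and 29.3% as
  printed; the sub-half-point discrepancies are consistent with parameter
  rounding and are not tuned away.
- **EM decomposition**: standard two-component univariate Gaussian EM in
  log space, convergence at <1e-8 log-likelihood gain or 500 iterations,
  monotone by construction, variance floor at 1e-3 of the data sd (flagged
  when triggered), identical initial components flagged unidentifiable.
  Two protocols are provided because the anchoring question is genuinely
  open: the default re-estimates all five parameters from the
  reference initialization; `freeze_components=True` fixes the component
  parameters at the sorted-lineage reference fits and estimates only the
  weights. At realistic scale (n ≈ 500, component separation ≈ 2 sd) the
  fully-free fit leaves α weakly identified — independent implementations
  converge to the same optimum with |α̂ − α| routinely exceeding 0.1 —
  whereas the anchored protocol recovers α to ~0.02 on average. When the
  goal is the lineage fraction of a mixture whose component phenotypes are
  known from sorted populations, the anchored variant is the appropriate
  estimator and is what the accuracy guarantee (mean |α̂ − α| ≤ 0.05) is
  stated for.
- **Tests**: χ² on the 2×3 recovery contingency table (no continuity
  correction); equal-length wCDI samples are compared with a paired t-test
  (screens are run at matched n), unequal lengths fall back to Welch and
  say so.

## Problem sizes

The validation suite runs the full chain on 200-cell seeded screens
(noise-free and SNR-20), 20×500-value EM replicates, and 100-point
property sweeps; the whole suite completes in a few seconds on one core.
These sizes were chosen as the smallest at which the population-level
guarantees are statistically meaningful.

## Known limitations

- Coincidence events are rejected, not deconvolved (no matched filtering);
  sinusoidal contraction geometries and viscoelastic frequency-domain
  models are out of scope.
- ΔT_r resolution is bounded by the post-pore spacing; sub-spacing recovery
  dynamics are unobservable by construction.
- U_flow uses the cell's own pore transit speed as a proxy for fluid
  velocity, which slightly underestimates the fluid speed for large cells.
- The occlusion proportionality constant and the effective diameter are
  device properties; results across devices are comparable only after
  microsphere calibration.
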