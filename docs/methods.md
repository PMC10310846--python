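# Methods

## Scope and structure

`sqifc` models a square-wave-excited impedance flow cytometer as four layers:
ground-truth circuit models (`sqifc.circuits`), the square-wave/PSD forward
measurement chain (`sqifc.psd`), calibration plus the square-to-sine
correction (`sqifc.correction`), and the particle event pipeline
(`sqifc.pipeline`) fed either by real instrument exports or by the synthetic
stream generator (`sqifc.synthesis`). The hardware itself (PCB, microfluidics,
MCU firmware, quadrature clock generation) is out of scope, as are dielectric
shell models of cells: the package treats the sample as a lumped R/C network
for EIS and as an amplitude-only pulse source for IFC.

## Conventions and the forward model

* **Phase sign.** Impedance is stored as a plain complex number;
  θ = atan2(Im Z, Re Z), so capacitive samples have θ < 0. The PSD
  quadrature output of a capacitive sample is positive, and the polar
  reconstruction θ = −atan2(Im, Re) returns the circuit convention.
* **Square-wave prefactor.** A ±V₀ square wave is synthesized as
  (4/π)V₀ Σ sin(nω₀t)/n. The prefactor is fixed by requiring that the
  time-domain reconstruction converge to peaks of ±V₀ against a
  sign-function oracle; V₀ is half the peak-to-peak drive (50 mV default for
  a 100 mVpp excitation, chosen to keep cells in their linear, unharmed
  regime).
* **Mixer constant.** Bipolar ±1 mixing of the (4/π)/n excitation harmonics
  with the (4/π)/n reference harmonics gives DC gain K = 8/π² per matching
  harmonic; the time-domain simulator confirms this to <0.1%. K is a config
  field (`k_psd`) because descriptions of this architecture differ in the
  printed constant; every corrected impedance and every ratio is invariant
  to it, only raw voltages change.
* **Quadrature harmonic signs.** The quadrature square reference
  sign(cos ω₀t) carries harmonic signs s_n = (−1)^((n−1)/2). These signs
  appear in the quadrature DC output and must be used again when subtracting
  harmonic contributions; omitting them leaves a phase error several times
  the correction's target precision.
* **TIA sign.** The inverting transimpedance stage's minus sign is dropped
  (readings are reported in the non-inverted convention), matching how the
  demodulated outputs are usually quoted.
* **Harmonic count.** Six odd harmonics (n = 1…11) by default: for a 10 MHz
  fundamental the retained harmonics reach 110 MHz, beyond which the chain's
  own roll-off makes contributions negligible.
* **Roll-off.** Finite TIA bandwidth is modelled as a single real pole at
  1/(2π R_f C_f) (plus an optional explicit cutoff), applied as a magnitude
  factor per harmonic. Parasitic coupling beyond a single pole is not
  modelled; on the real instrument it is absorbed by calibration, which is
  exactly how the package treats it too.

The time-domain simulator exists purely as an independent oracle: it builds
the TIA output per harmonic, multiplies by ±1 references sampled at midpoints
of a grid aligned with the switching edges (so every discontinuity falls
exactly between samples and the period average converges at O(1/N²)), and
averages over whole periods. It shares no code path with the closed-form
harmonic sum.

## Calibration and square-to-sine correction

Calibration factors are built per frequency as (ideal parasitic-free reading
for the known resistor) / (observed reading), averaged over reference
resistors; for a linear chain the factors are independent of the reference
value, which is tested. The "ideal" here still contains the square-wave
harmonics — calibration removes electronics parasitics only, and the
square-to-sine stage owns all harmonic removal.

The correction subtracts, from the calibrated reading at ω₀, the
1/n²-weighted readings at each odd harmonic frequency nω₀ (n ≤ 11) that lies
inside the swept grid, with log-frequency linear interpolation between grid
points (the grid is logarithmic, so nω₀ rarely lands on a point). Two modes
exist: *literal* subtracts raw calibrated readings; *recursive* (default)
processes the grid from the top down and subtracts already-corrected values,
removing second-order contamination — it is never worse than literal on the
validation circuits, which is tested.

Harmonics above the grid cannot be measured. Following the instrument's own
practice, no measured data is extrapolated: those terms are never subtracted,
and their 1/n² weight is reported per frequency in `residual_flag`
(0 = all harmonics measurable, 1 = none). By default the reconstruction then
divides by the weight of the terms actually accounted for
(`assume_flat_above_grid=True`), which treats the unmeasurable upper spectrum
as flat. This is exact for resistive samples, is what keeps the corrected
spectrum accurate in the top fraction of the band where no harmonic is
observable, and costs nothing where all harmonics are in-grid (the divisor is
then 1). For strongly capacitive samples whose |Z| keeps falling above the
grid it under-corrects — visible as growing error together with a non-zero
residual flag — which mirrors the physical instrument's documented
high-frequency bias. Setting `assume_flat_above_grid=False` gives the strict
printed form of the subtraction.

With the default 25 points/decade grid over 20 kHz–12 MHz, the corrected
spectrum of the validation circuit (10 kΩ in series with 4.7 kΩ ∥ 100 pF)
agrees with its analytic impedance to ~0.1% in magnitude over
100 kHz–10 MHz. Phase error is quoted in percent of the largest in-band
phase magnitude (|θ|max ≈ 10.8° for this circuit), since a plain relative
error diverges where θ crosses zero.

The two reported values of the validation circuit's parallel resistor
(4.7 kΩ in the text, 4.47 kΩ in one figure) are both provided
(`validation_circuit()`, `validation_circuit_alt()`); the default is 4.7 kΩ.

## Synthetic event streams

The generator emulates single-frequency burst-sampled acquisition at
5461 Sps: each particle contributes one unimodal impedance-magnitude pulse
per electrode pair with peak amplitudes summing to
height_factor · (D/G)³ — so the cube-root sizing relation inverts the
generator exactly at height factor 1 — and a channel-2 lag of L/velocity
(L = 406 µm). Pulse shape is a free choice (only amplitude and timing enter
the measurands): beads and cells are Gaussian with FWHM = electrode span /
velocity (span 203 µm default); bubbles are rendered overlong (3×) and
asymmetric (exponential tail); debris as near-single-sample spikes. The
height factor models the weaker field seen by particles travelling high in
the channel as a pure amplitude scale in (0, 1]; the multi-electrode
prominence correction that a 5-electrode layout enables is *not* implemented
— the generator exposes the effect, the pipeline does not correct it.

Defaults are the instrument's operating point: G = 10, 2%-of-amplitude
Gaussian noise (4 Ω against ~200 Ω pulses), a slow 20 Ω sinusoidal drift,
64-sample trigger bursts, 0.14 m/s transit velocity for populations, and a
50/50 ± 5% split of the summed amplitude across the two pairs. Streams are
stored as impedance-magnitude difference in ohms; conversion from PSD volts
to ohms is assumed done upstream by the correction stage.

What the generator does **not** emulate: hydrodynamics and electrokinetics,
coincident/overlapping transits (populations are spaced to avoid overlap,
with extra spacing after bubbles so their tails cannot bleed into the next
transit), conductivity–temperature drift of the buffer, and channel-geometry
deformation under flow pressure. Passing the recovery tests therefore shows
the *processing chain* is unbiased and correctly inverted under realistic
noise — not that real-channel physics is captured.

## Event pipeline choices

* **Baseline.** The slow baseline is the level-7 `db4` wavelet approximation
  (scale ≈ 23 ms at 5461 Sps, far above few-ms pulses, below seconds-scale
  drift), computed on a 55-sample running median of the stream so sparse
  pulses cannot leak into their own baseline and clip themselves. Streams
  shorter than one decomposition block fall back to median subtraction with
  a warning.
* **Denoising.** Zero-phase 4th-order Butterworth low-pass at sampling/8
  (≈683 Hz), then a 5-sample quadratic Savitzky–Golay smoother; SG is used
  rather than a moving average because it preserves Gaussian peak amplitudes
  to <1% at the default pulse widths where a boxcar clips ~10%. Peak times
  shift by less than one sample (tested).
* **Detection.** Local maxima above max(5 robust sigma, one tenth of the
  smallest reportable particle's per-channel amplitude); the absolute floor
  exists so noise-free streams do not trigger on numerical ripple. Peak time
  and amplitude are refined by a parabolic fit through the three samples
  around each maximum — without sub-sample timing, velocity is quantised at
  ~6% per sample at the default Δt.
* **Pairing.** Candidate (channel-1, channel-2) pairs within the lag window
  are consumed globally in order of increasing lag, so one missed or spurious
  peak cannot cascade into mispairing a run of events. Lags below half the
  physical minimum L/v_max are never candidates; the window tops out at 3×
  the lag of the slowest configured velocity.
* **Classification.** Hand-written labeling functions vote accept/reject/
  abstain: minimum 5 samples over the full two-pair transit, amplitude at
  least the 45 µm equivalent (expressed in ohms through the current G, so the
  threshold tracks calibration), physically plausible lag, pulse-width/
  velocity consistency, and pulse symmetry; a sixth function votes *accept*
  when all checks pass at once. Majority vote decides, and every rejected
  event records which functions voted against it. This is a deliberately
  simple stand-in for a learned weak-supervision label model.
* **Throughput ceiling.** The 5-point rule over the full 2L = 812 µm sensing
  span at 5461 Sps puts the fastest resolvable transit at 0.89 m/s.
* **Sizing.** G is fitted by least squares of D against (ΔZ₁+ΔZ₂)^{1/3}
  through the origin; the fit is exact on noiseless synthetic events and
  recovers G within 2% at 5% amplitude noise with 100 references (tested).
  Diameters are reported to 0.1 µm; histograms enforce the 45 µm minimum
  reportable size.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic data:
sweeps at 25 points/decade, oracle comparisons on 25 random RC networks × 5
frequencies, and particle populations of 200 (recovery) and 447 + 170
(classifier statistics, mirroring a realistic bead-to-outlier event ratio) —
sizes chosen so the full suite completes in seconds while leaving the
statistical assertions well-conditioned. All randomness flows through
explicit integer seeds; streams are bit-reproducible and the pipeline is
deterministic given stream and configuration.

## Known limitations

* The correction's flat-spectrum assumption above the grid under-corrects
  strongly capacitive samples near the top of the band (flagged, not fixed).
* Op-amp nonlinearities (slew rate, finite GBW) and ADC quantisation are not
  modelled; the single-pole roll-off plus calibration is the whole parasitics
  story here.
* The classifier is rule-based; its per-event acceptance probability under
  outlier load (~0.97) reflects pairing interference from bubble/debris
  peaks, not a trained error model.
* Coincident particles are neither generated nor resolved.
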