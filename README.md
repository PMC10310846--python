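# sqifc — square-wave impedance flow cytometry toolkit

`sqifc` models the measurement chain of a portable impedance flow cytometer
that replaces the usual sine-wave lock-in electronics with square-wave
excitation and switching phase-sensitive detectors (PSDs), and implements the
signal processing such an instrument needs: the harmonic-cancelling
"square-to-sine" spectroscopy correction, and the particle event detection,
classification and sizing pipeline. It is aimed at people designing or
analysing data from coplanar-electrode microfluidic impedance sensors —
single-cell counting and sizing of particles in the tens-of-micrometre range
(algae, buccal cells, microplastic beads).

## The model

**Electrical impedance spectroscopy (EIS).** The sample is a lumped
series/parallel network of resistors and capacitors with complex impedance
`Z(ω) = |Z| e^{jθ}` (capacitive samples have θ < 0). A ±V₀ square wave has
the Fourier expansion

    V_in(t) = (4/π) V₀ Σ_{n odd} sin(n ω₀ t)/n ,

so every odd harmonic of the fundamental drives the sample simultaneously.
After the transimpedance amplifier (gain R_f) a pair of switching mixers
(±1 references, in phase and in quadrature with the fundamental) demodulates
the current response, folding each harmonic to DC:

    Re = K V₀ R_f Σ_{n odd} cos θ(nω₀) / (n² |Z(nω₀)|)
    Im = K V₀ R_f Σ_{n odd} s_n sin θ(nω₀) / (n² |Z(nω₀)|)

with K = 8/π² for bipolar mixing and s_n = (−1)^((n−1)/2) the alternating
signs of the quadrature reference's harmonics. Both a closed-form evaluation
and a brute-force time-domain simulation of this chain are provided, and they
are tested against each other.

**Square-to-sine correction.** The harmonic terms (n ≥ 3) are a systematic
error relative to a sine measurement. After calibrating the chain on known
resistors, the correction subtracts the 1/n²-weighted readings measured at
each harmonic frequency that lies inside the swept grid, recursively from the
top of the grid down, and reconstructs

    |Z(ω₀)| = K V₀ R_f / √(Re² + Im²) ,   θ(ω₀) = −atan2(Im, Re).

Harmonics above the grid are unmeasurable; their omitted weight is reported
per frequency in a residual flag, and by default the reconstruction assumes
the spectrum is flat beyond the grid (exact for resistive samples).

**Impedance flow cytometry (IFC).** A particle transiting the microchannel
produces one impedance-magnitude pulse per electrode pair, the second lagging
the first by Δt = L/v (L = 406 µm pair separation). The Coulter-style sizing
relation

    D = G (|ΔZ₁| + |ΔZ₂|)^{1/3}

maps the summed pulse amplitudes to particle diameter, where G is an
empirical constant fitted on beads of known diameter. The pipeline removes
the baseline by wavelet decomposition, denoises and smooths, detects peaks,
pairs them across channels, classifies events with rule-based labeling
functions combined by majority vote (rejecting bubbles, debris, and
too-fast transits with fewer than 5 samples), and reports diameters,
velocities and population histograms.

A synthetic-stream generator produces two-channel event streams with known
ground truth (diameters, velocities, heights, bubbles/debris, drift, noise,
burst-triggered acquisition) so every stage is testable against the truth
table.

## Worked example

```python
import numpy as np
from sqifc import psd, correction as corr, synthesis as syn, pipeline as pl
from sqifc.circuits import validation_circuit, resistor

# --- EIS: simulate, calibrate, correct the validation circuit ---
cfg = psd.ExcitationConfig()                      # 100 mVpp, 6 odd harmonics
sweep = psd.sweep_eis(cfg, validation_circuit(), 20e3, 12e6, 25, channels=(1,))
ref   = psd.sweep_eis(cfg, resistor(10e3), 20e3, 12e6, 25, channels=(1,))
table = corr.build_calibration([(10e3, ref)], cfg)
out   = corr.square_to_sine(corr.apply_calibration(sweep, table), cfg)

# --- IFC: synthesize a bead stream and run the event pipeline ---
scfg = syn.StreamConfig(seed=42)
particles = syn.random_particles(scfg, n_beads=50, n_bubbles=5, n_debris=5, seed=42)
stream, truth = syn.synthesize_stream(scfg, particles)
events = pl.run_pipeline(stream, pl.PipelineConfig())
```

Output (printing band error, one spectrum point, and pipeline results):

```
max |Z| error in band: 0.100 %
at 1017674 Hz: |Z| = 10564.0 ohm, theta = -7.65 deg
true:       |Z| = 10580.3 ohm, theta = -7.76 deg
accepted 48 of 86 detection events
diameter median 71.8 um, IQR 9.5 um, range 62.9-81.1 um
first event: dz1=237 ohm dz2=256 ohm dt=2.91 ms v=0.140 m/s D=79.0 um
```

The corrected spectrum of the 10 kΩ + (4.7 kΩ ∥ 100 pF) validation circuit
agrees with its analytic impedance to 0.1% across 100 kHz–10 MHz; 48 of the
50 synthetic beads are accepted (86 detection events include the bubble,
debris and unmatched-peak rejections), and a bead with ΔZ₁ = 237 Ω,
ΔZ₂ = 256 Ω sizes to 79 µm at G = 10 with a transit velocity of 0.14 m/s.

The same steps are available from a shell:

```sh
sqifc simulate-eis --out sweep.csv
sqifc simulate-stream --n-beads 50 --seed 42 --out stream.csv --truth truth.csv
sqifc detect --in stream.csv --out events.csv --histogram hist.csv
```

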