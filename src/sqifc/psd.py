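"""Square-wave excitation and phase-sensitive detection forward model.

The measurement chain simulated here is: a ±V0 square wave drives the sample
impedance; the resulting current is converted to a voltage by a transimpedance
amplifier (TIA, gain Rf); two phase-sensitive detectors mix that voltage with
±1 square references (in-phase and quadrature at the fundamental) and low-pass
to DC.  Because the excitation carries every odd harmonic with amplitude 1/n,
and the bipolar square references carry matching odd harmonics, each harmonic
of the excitation is demodulated to DC alongside the fundamental:

    re_v = K · V0 · Rf · Σ_odd  |H(n f0)| · cos θ(n f0) / (n² |Z(n f0)|)
    im_v = K · V0 · Rf · Σ_odd  |H(n f0)| · s_n · sin θ(n f0) / (n² |Z(n f0)|)

with θ the phase of 1/Z (so a capacitive sample gives im_v > 0), s_n the
alternating sign (−1)^((n−1)/2) carried by the quadrature reference's
harmonics, and |H| an optional single-pole roll-off modelling the finite TIA
bandwidth.  K is the mixer gain constant: bipolar ±1 mixing gives K = 8/π²
(confirmed against the time-domain oracle in this module); the constant is
configurable since every corrected impedance is invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circuits import CircuitModel

__all__ = [
    "K_PSD_BIPOLAR",
    "K_PSD_PRINTED",
    "ExcitationConfig",
    "PsdReading",
    "square_wave_samples",
    "harmonic_numbers",
    "quadrature_signs",
    "harmonic_attenuation",
    "psd_dc_analytic",
    "psd_dc_for_circuit",
    "psd_dc_timedomain",
    "sweep_eis",
]

# Mixer gain for bipolar (+1/-1) square references: (4/pi) excitation harmonic
# amplitude x (4/pi) reference harmonic amplitude x 1/2 from the product of
# two unit sinusoids.
K_PSD_BIPOLAR = 8.0 / np.pi**2
# Constant printed alongside the demodulation equations in some descriptions
# of this architecture; selectable for literal reproduction.
K_PSD_PRINTED = 0.5 * 6.0 / np.pi**2


class PsdConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ExcitationConfig:
    """Square-wave excitation and detection-chain parameters.

    v0 is half the peak-to-peak excitation (50 mV for the 100 mVpp drive used
    on live cells); f0 the fundamental; n_harmonics the number of odd
    harmonics retained (6 keeps n = 1..11, reaching 110 MHz harmonics for a
    10 MHz fundamental); rf/cf the TIA feedback network (cf > 0 adds a real
    pole at 1/(2π·rf·cf)); bandwidth_hz an extra explicit single-pole cutoff.
    """

    v0: float = 0.05
    f0: float = 1e6
    n_harmonics: int = 6
    rf: float = 10e3
    cf: float = 0.0
    bandwidth_hz: float | None = None
    k_psd: float = K_PSD_BIPOLAR

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise PsdConfigError("v0 must be >= 0")
        if self.f0 <= 0:
            raise PsdConfigError("f0 must be > 0")
        if self.n_harmonics < 1:
            raise PsdConfigError("n_harmonics must be >= 1")
        if self.rf <= 0:
            raise PsdConfigError("rf must be > 0")
        if self.cf < 0:
            raise PsdConfigError("cf must be >= 0")

    def at(self, f0: float) -> "ExcitationConfig":
        """Same chain retuned to a new fundamental frequency."""
        return replace(self, f0=f0)


@dataclass(frozen=True)
class PsdReading:
    """DC outputs of one electrode channel's quadrature PSD pair."""

    frequency: float
    re_v: float
    im_v: float
    channel: int = 1

    def __post_init__(self) -> None:
        if self.channel not in (1, 2):
            raise ValueError("channel must be 1 or 2")
        if not (np.isfinite(self.re_v) and np.isfinite(self.im_v)):
            raise ValueError("PSD outputs must be finite")


def harmonic_numbers(cfg: ExcitationConfig) -> np.ndarray:
    """Odd harmonic orders included in the model: 1, 3, ..., 2*n_harmonics-1."""
    return np.arange(1, 2 * cfg.n_harmonics, 2)


def quadrature_signs(n: np.ndarray) -> np.ndarray:
    """Signs (−1)^((n−1)/2) of the odd harmonics of a bipolar cosine square wave."""
    return np.where(((n - 1) // 2) % 2 == 0, 1.0, -1.0)


def harmonic_attenuation(cfg: ExcitationConfig, frequencies: np.ndarray) -> np.ndarray:
    """|H(f)| of the chain's single-pole roll-offs (TIA feedback pole and/or
    an explicit bandwidth limit); 1 when neither is configured."""
    h = np.ones_like(frequencies, dtype=float)
    if cfg.cf > 0:
        fc = 1.0 / (2.0 * np.pi * cfg.rf * cfg.cf)
        h /= np.sqrt(1.0 + (frequencies / fc) ** 2)
    if cfg.bandwidth_hz is not None:
        h /= np.sqrt(1.0 + (frequencies / cfg.bandwidth_hz) ** 2)
    return h


def square_wave_samples(cfg: ExcitationConfig, times: Iterable[float]) -> np.ndarray:
    """Truncated Fourier synthesis of the ±v0 square wave at the given times.

    V(t) = (4/π) v0 Σ_odd sin(2π n f0 t)/n; as n_harmonics → ∞ the
    reconstruction converges to v0·sign(sin(2π f0 t)) away from transitions.
    """
    t = np.asarray(times, dtype=float)
    if np.any(~np.isfinite(t)):
        raise ValueError("times must be finite")
    n = harmonic_numbers(cfg)
    phases = 2.0 * np.pi * cfg.f0 * np.multiply.outer(t, n)
    return (4.0 / np.pi) * cfg.v0 * np.sin(phases) @ (1.0 / n)


def _z_at_harmonics(cfg: ExcitationConfig, z) -> np.ndarray:
    """Normalise the per-harmonic impedance argument to a complex array."""
    n = harmonic_numbers(cfg)
    if hasattr(z, "impedance"):
        return z.impedance(n * cfg.f0)
    z = list(z)
    vals = []
    for item in z:
        if hasattr(item, "z"):  # duck-typed ImpedancePoint-style records
            vals.append(complex(item.z))
        else:
            vals.append(complex(item))
    return np.asarray(vals, dtype=complex)


def psd_dc_analytic(
    cfg: ExcitationConfig,
    z_at_harmonics,
    channel: int = 1,
    allow_truncation: bool = False,
    max_harmonic_hz: float | None = None,
) -> PsdReading:
    """DC PSD outputs from the closed-form harmonic sum.

    ``z_at_harmonics`` supplies Z(n·f0) for each included odd n, either as a
    sequence of complex values (ordered n = 1, 3, 5, ...) or as a
    :class:`~sqifc.circuits.CircuitModel`.  A sequence shorter than the
    configured harmonic count is an error unless ``allow_truncation``.
    ``max_harmonic_hz`` excludes harmonics above that frequency entirely
    (used to emulate an excitation whose harmonics all fall inside a
    measured grid).
    """
    n = harmonic_numbers(cfg)
    z = _z_at_harmonics(cfg, z_at_harmonics)
    if not hasattr(z_at_harmonics, "impedance"):
        if len(z) < len(n):
            if not allow_truncation:
                raise ValueError(
                    f"impedance given for {len(z)} harmonics, "
                    f"{len(n)} required (pass allow_truncation=True to permit)"
                )
            n = n[: len(z)]
        z = z[: len(n)]
    if max_harmonic_hz is not None:
        keep = n * cfg.f0 <= max_harmonic_hz * (1.0 + 1e-9)
        if not keep[0]:
            raise ValueError("max_harmonic_hz excludes the fundamental")
        n, z = n[keep], z[keep]
    if np.any(z == 0):
        raise ValueError("zero impedance at a harmonic")
    y = 1.0 / z  # admittance; Re(y) = cosθz/|Z|, Im(y) = −sinθz/|Z|
    w = harmonic_attenuation(cfg, n * cfg.f0) / n.astype(float) ** 2
    scale = cfg.k_psd * cfg.v0 * cfg.rf
    re = scale * float(np.sum(w * y.real))
    im = scale * float(np.sum(w * quadrature_signs(n) * y.imag))
    return PsdReading(cfg.f0, re, im, channel)


def psd_dc_for_circuit(
    cfg: ExcitationConfig, model: CircuitModel, channel: int = 1
) -> PsdReading:
    return psd_dc_analytic(cfg, model, channel=channel)


def psd_dc_timedomain(
    cfg: ExcitationConfig,
    model: CircuitModel,
    n_periods: int = 16,
    samples_per_period: int = 512,
    channel: int = 1,
) -> PsdReading:
    """Brute-force oracle: synthesise the waveforms and mix with ±1 switches.

    The TIA output is built per harmonic as a phase-shifted sinusoid through
    Z(n f0), multiplied sample-by-sample by the signs of the in-phase and
    quadrature references, and averaged over whole periods.  Samples are taken
    at midpoints of a grid aligned with the reference transitions
    (samples_per_period divisible by 4), so every switching edge falls exactly
    between two samples and the period average converges at O(1/N²).
    """
    if int(n_periods) != n_periods or n_periods < 1:
        raise ValueError("n_periods must be a positive integer (whole periods)")
    if samples_per_period < 64:
        raise ValueError("samples_per_period must be >= 64")
    if samples_per_period % 4:
        raise ValueError("samples_per_period must be divisible by 4")
    n = harmonic_numbers(cfg)
    z = model.impedance(n * cfg.f0)
    y = 1.0 / z
    amp = (4.0 / np.pi) * cfg.v0 * cfg.rf * harmonic_attenuation(cfg, n * cfg.f0) / n
    total = int(n_periods) * samples_per_period
    # midpoint sampling of phase within each period
    phase = 2.0 * np.pi * (np.arange(total) + 0.5) / samples_per_period
    # i_n(t) = |y_n| sin(n ω t + arg y_n); v_tia = Rf Σ amp_n |y_n| sin(...)
    v_tia = np.zeros(total)
    for k, order in enumerate(n):
        v_tia += amp[k] * np.abs(y[k]) * np.sin(order * phase + np.angle(y[k]))
    ref_i = np.sign(np.sin(phase))
    ref_q = np.sign(np.cos(phase))
    return PsdReading(
        cfg.f0, float(np.mean(v_tia * ref_i)), float(np.mean(v_tia * ref_q)), channel
    )


def log_frequency_grid(f_start: float, f_stop: float, points_per_decade: int) -> np.ndarray:
    """Logarithmic grid including both endpoints."""
    if not (0 < f_start < f_stop):
        raise ValueError("need 0 < f_start < f_stop")
    decades = np.log10(f_stop / f_start)
    n_points = max(2, int(np.ceil(decades * points_per_decade)) + 1)
    return np.geomspace(f_start, f_stop, n_points)


def sweep_eis(
    cfg: ExcitationConfig,
    model: CircuitModel,
    f_start: float = 20e3,
    f_stop: float = 12e6,
    points_per_decade: int = 25,
    channels: Sequence[int] = (1, 2),
    noise_sigma_v: float = 0.0,
    seed: int | None = None,
    max_harmonic_hz: float | None = None,
) -> pd.DataFrame:
    """Simulated EIS sweep: PSD readings on a log grid, per electrode channel.

    Returns a frame with columns frequency_hz, channel, re_v, im_v and a
    ``stage`` column set to "raw".  Optional additive Gaussian noise (volts)
    is reproducible under a fixed seed.  ``max_harmonic_hz`` restricts the
    excitation's harmonic content (see :func:`psd_dc_analytic`).
    """
    grid = log_frequency_grid(f_start, f_stop, points_per_decade)
    rng = np.random.default_rng(seed)
    rows = []
    for ch in channels:
        for f in grid:
            r = psd_dc_analytic(
                cfg.at(f), model, channel=ch, max_harmonic_hz=max_harmonic_hz
            )
            re, im = r.re_v, r.im_v
            if noise_sigma_v > 0:
                re += rng.normal(0.0, noise_sigma_v)
                im += rng.normal(0.0, noise_sigma_v)
            rows.append((f, ch, re, im))
    df = pd.DataFrame(rows, columns=["frequency_hz", "channel", "re_v", "im_v"])
    df["stage"] = "raw"
    return df
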