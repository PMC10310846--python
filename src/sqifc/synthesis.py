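"""Synthetic two-channel particle event streams with known ground truth.

Emulates the burst-sampled single-frequency acquisition: each particle
transiting the microchannel produces one smooth impedance-magnitude pulse per
electrode pair, the second lagging the first by L/velocity.  Peak amplitudes
per pair sum to (D/G)³ scaled by a height factor (particles travelling higher
in the channel see a weaker field and read smaller), so the cube-root sizing
relation inverts the generator exactly before noise.  Bubbles and debris get
deliberately non-bead-like pulse shapes so rule-based classifiers have
something to reject.

Streams are stored as impedance-magnitude difference in ohms; the conversion
from PSD volts to ohms is the correction module's job and is assumed done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParticleTruth",
    "StreamConfig",
    "pulse_amplitudes",
    "synthesize_stream",
    "random_particles",
    "burst_sample",
]

PARTICLE_KINDS = ("bead", "cell", "bubble", "debris")


@dataclass(frozen=True)
class ParticleTruth:
    """Ground truth for one particle transit."""

    diameter_um: float
    velocity_mps: float
    entry_s: float
    height_factor: float = 1.0
    kind: str = "bead"
    split_fraction: float = 0.5  # fraction of the summed ΔZ seen by pair 1

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")
        if self.velocity_mps <= 0:
            raise ValueError("velocity must be > 0")
        if not 0 < self.height_factor <= 1:
            raise ValueError("height factor must be in (0, 1]")
        if self.kind not in PARTICLE_KINDS:
            raise ValueError(f"kind must be one of {PARTICLE_KINDS}")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must be in (0, 1)")


@dataclass(frozen=True)
class StreamConfig:
    """Acquisition and channel geometry parameters.

    Defaults mirror the instrument's operating point: 5461 Sps sampling,
    64-sample bursts, 406 µm between electrode pairs in a 180 µm channel,
    sizing constant G = 10 (so a 78 µm bead gives ΔZ1+ΔZ2 ≈ 480 Ω).
    """

    sampling_rate_sps: float = 5461.0
    burst_len: int = 64
    pair_separation_um: float = 406.0
    channel_width_um: float = 180.0
    electrode_span_um: float = 203.0
    sizing_constant_g: float = 10.0
    baseline_ohm: float = 0.0
    noise_sigma_ohm: float = 4.0
    drift_amplitude_ohm: float = 20.0
    drift_period_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_sps <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.pair_separation_um <= 0:
            raise ValueError("pair separation must be > 0")
        if self.burst_len < 1:
            raise ValueError("burst length must be >= 1")
        if self.noise_sigma_ohm < 0 or self.drift_amplitude_ohm < 0:
            raise ValueError("noise/drift amplitudes must be >= 0")

    @property
    def sensing_span_um(self) -> float:
        """Full two-pair sensing span used for the transit-duration rule (2L)."""
        return 2.0 * self.pair_separation_um


def pulse_amplitudes(
    diameter_um: float,
    g: float,
    height_factor: float = 1.0,
    split_fraction: float = 0.5,
) -> tuple[float, float]:
    """Per-pair peak amplitudes (ohms) whose sum inverts the sizing relation.

    A1 + A2 = height_factor · (D/G)³, so G·(A1+A2)^(1/3) returns D exactly
    at height factor 1.
    """
    total = height_factor * (diameter_um / g) ** 3
    return split_fraction * total, (1.0 - split_fraction) * total


def _pulse_shape(t: np.ndarray, center: float, sigma_s: float, kind: str) -> np.ndarray:
    """Unit-peak pulse template; bubbles and debris are intentionally odd."""
    if kind in ("bead", "cell"):
        return np.exp(-0.5 * ((t - center) / sigma_s) ** 2)
    if kind == "bubble":
        # overlong, asymmetric: gaussian rise, slower exponential tail
        rise = np.exp(-0.5 * ((t - center) / sigma_s) ** 2)
        tail = np.exp(-(t - center) / (3.0 * sigma_s))
        return np.where(t < center, rise, tail)
    # debris: a near-single-sample spike
    return np.exp(-0.5 * ((t - center) / (0.25 * sigma_s)) ** 2)


def synthesize_stream(
    cfg: StreamConfig,
    particles: Sequence[ParticleTruth],
    duration_s: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the two-channel stream and its truth table.

    Returns ``(stream, truth)``: the stream has columns time_s, ch1_dz_ohm,
    ch2_dz_ohm; the truth table one row per particle including the per-pair
    peak amplitudes and peak times.  Bit-reproducible under ``cfg.seed``.
    """
    fs = cfg.sampling_rate_sps
    l_sep = cfg.pair_separation_um * 1e-6
    span = cfg.electrode_span_um * 1e-6
    if duration_s is None:
        t_end = 0.5
        for p in particles:
            t_end = max(t_end, p.entry_s + (span + l_sep + 6 * span) / p.velocity_mps)
        duration_s = t_end + 0.05
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(cfg.seed)
    drift = cfg.drift_amplitude_ohm * np.sin(2 * np.pi * t / cfg.drift_period_s)
    ch = [
        cfg.baseline_ohm + drift + rng.normal(0.0, cfg.noise_sigma_ohm, n),
        cfg.baseline_ohm + drift + rng.normal(0.0, cfg.noise_sigma_ohm, n),
    ]

    rows = []
    for pid, p in enumerate(particles):
        if p.entry_s < 0 or p.entry_s > duration_s:
            raise ValueError(f"particle {pid} entry time outside the stream")
        a1, a2 = pulse_amplitudes(
            p.diameter_um, cfg.sizing_constant_g, p.height_factor, p.split_fraction
        )
        transit_s = span / p.velocity_mps
        detectable = True
        if transit_s * fs < 1.0:
            warnings.warn(
                f"particle {pid}: transit ({transit_s * 1e3:.3f} ms) faster than "
                "one sample over the electrode span; undetectable",
                stacklevel=2,
            )
            detectable = False
        sigma_s = transit_s / 2.355  # FWHM = electrode span / velocity
        if p.kind == "bubble":
            sigma_s *= 3.0  # overlong
        c1 = p.entry_s + 0.5 * transit_s
        c2 = c1 + l_sep / p.velocity_mps
        for idx, (center, amp) in enumerate(((c1, a1), (c2, a2))):
            lo = max(0, int((center - 12 * sigma_s * 6) * fs))
            hi = min(n, int((center + 12 * sigma_s * 6) * fs) + 1)
            if hi > lo:
                ch[idx][lo:hi] += amp * _pulse_shape(t[lo:hi], center, sigma_s, p.kind)
        rows.append(
            {
                "particle_id": pid,
                "kind": p.kind,
                "diameter_um": p.diameter_um,
                "velocity_mps": p.velocity_mps,
                "entry_s": p.entry_s,
                "height_factor": p.height_factor,
                "a1_ohm": a1,
                "a2_ohm": a2,
                "t_peak1_s": c1,
                "t_peak2_s": c2,
                "detectable": detectable,
            }
        )
    stream = pd.DataFrame({"time_s": t, "ch1_dz_ohm": ch[0], "ch2_dz_ohm": ch[1]})
    truth = pd.DataFrame(
        rows,
        columns=[
            "particle_id",
            "kind",
            "diameter_um",
            "velocity_mps",
            "entry_s",
            "height_factor",
            "a1_ohm",
            "a2_ohm",
            "t_peak1_s",
            "t_peak2_s",
            "detectable",
        ],
    )
    return stream, truth


def random_particles(
    cfg: StreamConfig,
    n_beads: int = 200,
    diameter_range_um: tuple[float, float] = (63.0, 83.0),
    velocity_mps: float = 0.14,
    n_bubbles: int = 0,
    n_debris: int = 0,
    height_factor_range: tuple[float, float] = (1.0, 1.0),
    split_asymmetry: float = 0.05,
    gap_factor: float = 6.0,
    seed: int | None = None,
    kind: str = "bead",
) -> list[ParticleTruth]:
    """Draw a non-overlapping particle population.

    Beads get diameters uniform over ``diameter_range_um`` (the validation
    population is 63–83 µm polyethylene beads); bubbles and debris are
    interleaved.  Entry times are spaced by ``gap_factor`` × the full transit
    duration so transits never overlap.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    l_sep = cfg.pair_separation_um * 1e-6
    span = cfg.electrode_span_um * 1e-6
    transit = (span + l_sep) / velocity_mps
    kinds = [kind] * n_beads + ["bubble"] * n_bubbles + ["debris"] * n_debris
    rng.shuffle(kinds)
    particles = []
    t = 0.05
    for k in kinds:
        if k in ("bead", "cell"):
            d = rng.uniform(*diameter_range_um)
        elif k == "bubble":
            d = rng.uniform(*diameter_range_um) * 1.3
        else:  # debris: small
            d = rng.uniform(20.0, 40.0)
        particles.append(
            ParticleTruth(
                diameter_um=d,
                velocity_mps=velocity_mps,
                entry_s=t,
                height_factor=rng.uniform(*height_factor_range),
                kind=k,
                split_fraction=0.5 + rng.uniform(-split_asymmetry, split_asymmetry),
            )
        )
        # bubbles are rendered overlong; leave extra room so their tails
        # cannot bleed into the next transit
        t += gap_factor * transit * (4.0 if k == "bubble" else 1.0)
    return particles


def burst_sample(
    stream: pd.DataFrame,
    trigger_threshold_ohm: float,
    cfg: StreamConfig | None = None,
    pretrigger: int = 8,
    background_decimation: int = 64,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event-triggered burst acquisition.

    Whenever either channel's baseline-subtracted value exceeds the trigger
    threshold, a burst of exactly ``burst_len`` consecutive samples (starting
    ``pretrigger`` samples before the crossing) is saved; between bursts the
    background is kept at a decimated rate.  Returns the burst-structured
    stream (with a ``burst_id`` column, −1 for background samples) and a
    table of burst boundaries.
    """
    if trigger_threshold_ohm <= 0:
        raise ValueError("trigger threshold must be > 0")
    cfg = cfg or StreamConfig()
    burst_len = cfg.burst_len
    ch1 = stream["ch1_dz_ohm"].to_numpy(float)
    ch2 = stream["ch2_dz_ohm"].to_numpy(float)
    base1, base2 = np.median(ch1), np.median(ch2)
    n = len(stream)
    exceed = (np.abs(ch1 - base1) > trigger_threshold_ohm) | (
        np.abs(ch2 - base2) > trigger_threshold_ohm
    )
    burst_id = np.full(n, -1, dtype=int)
    bounds = []
    i = 0
    k = 0
    while i < n:
        if exceed[i] and burst_id[i] < 0:
            start = min(max(0, i - pretrigger), max(0, n - burst_len))
            stop = start + burst_len
            burst_id[start:stop] = k
            bounds.append(
                {
                    "burst_id": k,
                    "start_index": start,
                    "stop_index": stop,
                    "start_s": float(stream["time_s"].iloc[start]),
                }
            )
            k += 1
            i = stop
        else:
            i += 1
    out = stream.copy()
    out["burst_id"] = burst_id
    keep = (burst_id >= 0) | (np.arange(n) % background_decimation == 0)
    return out.loc[keep].reset_index(drop=True), pd.DataFrame(
        bounds, columns=["burst_id", "start_index", "stop_index", "start_s"]
    )
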