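"""Particle event detection, classification, and sizing.

Processing chain for a two-channel impedance-difference stream:

1. baseline removal — the slow varying mean is estimated as the low-order
   approximation of a multi-resolution wavelet decomposition and subtracted;
2. denoising — zero-phase low-pass filtering plus Savitzky–Golay smoothing
   (peak times must not shift, peak amplitudes must survive);
3. peak detection — local maxima above an amplitude threshold, with the
   sample count at half maximum attached to each candidate;
4. pairing — nearest-in-time greedy matching of channel-1 and channel-2
   peaks; the transit time Δt = t2 − t1 gives velocity = L/Δt;
5. classification — hand-written labeling functions vote accept/reject/
   abstain per event (minimum point count, minimum amplitude, physically
   plausible lag, pulse-width/velocity consistency, pulse symmetry) and the
   votes are combined by majority;
6. sizing — D = G·(|ΔZ1| + |ΔZ2|)^(1/3), with G from a reference-bead fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, signal

__all__ = [
    "PipelineConfig",
    "SizingCalibration",
    "remove_baseline",
    "denoise_and_smooth",
    "detect_peaks",
    "pair_and_measure",
    "classify_events",
    "estimate_diameter",
    "calibrate_g",
    "population_histogram",
    "max_detectable_velocity",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CHANNEL_COLUMNS = ("ch1_dz_ohm", "ch2_dz_ohm")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables for the detection pipeline.

    Defaults assume the 5461 Sps acquisition: low-pass cutoff of sampling/8,
    a 5-sample quadratic Savitzky–Golay smoother, db4 baseline wavelet at
    level 7 (baseline scale ≈ 23 ms, far above the few-ms pulse widths),
    detection threshold at 5 robust sigma, and the 45 µm minimum reportable
    size expressed back in ohms through the current sizing constant.
    """

    sampling_rate_sps: float = 5461.0
    pair_separation_um: float = 406.0
    electrode_span_um: float = 203.0
    sensing_span_um: float = 812.0  # full two-pair span (2L)
    sizing_constant_g: float = 10.0
    lowpass_cutoff_hz: float | None = None  # default sampling/8
    smooth_window: int = 5
    smooth_polyorder: int = 2
    wavelet: str = "db4"
    wavelet_level: int = 7
    baseline_median_window: int = 55  # samples; must exceed 2x the pulse support
    threshold_sigma: float = 5.0
    min_points: int = 5
    min_diameter_um: float = 45.0
    min_velocity_mps: float = 0.01
    pairing_window_factor: float = 3.0
    min_separation_s: float | None = None
    symmetry_limit: float = 2.5
    width_consistency_band: tuple[float, float] = (0.4, 2.5)

    @property
    def cutoff_hz(self) -> float:
        return self.lowpass_cutoff_hz or self.sampling_rate_sps / 8.0

    @property
    def min_amplitude_ohm(self) -> float:
        """Eq.-2 inverse of the minimum reportable diameter at the current G,
        split across the two electrode pairs."""
        return (self.min_diameter_um / self.sizing_constant_g) ** 3

    @property
    def detection_floor_ohm(self) -> float:
        """Absolute lower bound on the peak threshold: one tenth of the
        per-channel amplitude of the smallest reportable particle, so a
        noise-free stream does not trigger on numerical ripple."""
        return 0.1 * self.min_amplitude_ohm / 2.0

    @property
    def max_lag_s(self) -> float:
        return self.pairing_window_factor * (
            self.pair_separation_um * 1e-6 / self.min_velocity_mps
        )


@dataclass(frozen=True)
class SizingCalibration:
    """Fitted sizing constant G (µm·Ω^(-1/3)) with its fit residual."""

    g: float
    residual_um: float = 0.0
    reference_diameters_um: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("G must be > 0")


def max_detectable_velocity(cfg: PipelineConfig) -> float:
    """Fastest transit (m/s) still yielding ``min_points`` samples over the
    full sensing span at the configured sampling rate."""
    return cfg.sensing_span_um * 1e-6 * cfg.sampling_rate_sps / cfg.min_points


# ---------------------------------------------------------------------------
# stage 1-2: conditioning
# ---------------------------------------------------------------------------


def _baseline_1d(x: np.ndarray, wavelet: str, level: int, median_window: int) -> np.ndarray:
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(len(x), w.dec_len)
    if max_level < 1:
        warnings.warn(
            "stream shorter than one wavelet block; falling back to median subtraction",
            stacklevel=3,
        )
        return np.full_like(x, np.median(x))
    # a running median first makes the estimate blind to sparse transit
    # pulses, which would otherwise leak into the approximation and clip
    # their own amplitude
    if median_window > 1 and len(x) > median_window:
        x = ndimage.median_filter(x, size=median_window, mode="nearest")
    level = min(level, max_level)
    coeffs = pywt.wavedec(x, w, level=level)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, w)[: len(x)]


def remove_baseline(stream: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Subtract the slow baseline (wavelet approximation of the running
    median) from each channel."""
    if stream.empty:
        raise ValueError("empty stream")
    out = stream.copy()
    for col in CHANNEL_COLUMNS:
        x = stream[col].to_numpy(float)
        out[col] = x - _baseline_1d(
            x, cfg.wavelet, cfg.wavelet_level, cfg.baseline_median_window
        )
    return out


def denoise_and_smooth(stream: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Zero-phase low-pass plus Savitzky–Golay smoothing (no peak-time shift)."""
    fs = cfg.sampling_rate_sps
    cutoff = cfg.cutoff_hz
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must be in (0, Nyquist={fs / 2})")
    sos = signal.butter(4, cutoff, fs=fs, output="sos")
    out = stream.copy()
    for col in CHANNEL_COLUMNS:
        x = signal.sosfiltfilt(sos, stream[col].to_numpy(float))
        if cfg.smooth_window > 1:
            x = signal.savgol_filter(x, cfg.smooth_window, cfg.smooth_polyorder)
        out[col] = x
    return out


# ---------------------------------------------------------------------------
# stage 3: peak detection
# ---------------------------------------------------------------------------


def robust_sigma(x: np.ndarray) -> float:
    """Noise scale from the median absolute deviation (outlier-immune)."""
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_peaks(
    stream: pd.DataFrame,
    cfg: PipelineConfig,
    threshold_ohm: float | None = None,
) -> pd.DataFrame:
    """Per-channel candidate peaks above threshold.

    Returns a frame with columns channel, index, time_s, amplitude_ohm,
    width_s, n_points (samples above half maximum) and symmetry (right/left
    half-width ratio).  The default threshold is ``threshold_sigma`` robust
    sigmas of the conditioned signal.
    """
    if stream.empty:
        return pd.DataFrame(
            columns=[
                "channel",
                "index",
                "time_s",
                "amplitude_ohm",
                "width_s",
                "n_points",
                "symmetry",
            ]
        )
    fs = cfg.sampling_rate_sps
    t = stream["time_s"].to_numpy(float)
    min_sep = cfg.min_separation_s
    if min_sep is None:
        min_sep = 0.5 * cfg.electrode_span_um * 1e-6 / max_detectable_velocity(cfg) * cfg.min_points
    distance = max(1, int(round(min_sep * fs)))
    rows = []
    for ch, col in enumerate(CHANNEL_COLUMNS, start=1):
        x = stream[col].to_numpy(float)
        thr = threshold_ohm
        if thr is None:
            thr = max(cfg.threshold_sigma * robust_sigma(x), cfg.detection_floor_ohm)
        peaks, _ = signal.find_peaks(x, height=thr, distance=distance)
        if len(peaks) == 0:
            continue
        widths, _, left_ips, right_ips = signal.peak_widths(x, peaks, rel_height=0.5)
        for p, w, li, ri in zip(peaks, widths, left_ips, right_ips):
            # parabolic vertex through the three samples around the maximum
            # gives sub-sample peak time and amplitude (velocity would
            # otherwise be quantised at the sampling interval)
            dt_sub, amp = 0.0, x[p]
            if 0 < p < len(x) - 1:
                a, b, c = x[p - 1], x[p], x[p + 1]
                denom = a - 2 * b + c
                if denom < 0:
                    dt_sub = 0.5 * (a - c) / denom
                    amp = b - 0.25 * (a - c) * dt_sub
            left = (p + dt_sub) - li
            right = ri - (p + dt_sub)
            rows.append(
                {
                    "channel": ch,
                    "index": int(p),
                    "time_s": t[p] + dt_sub / fs,
                    "amplitude_ohm": amp,
                    "width_s": w / fs,
                    "n_points": int(np.floor(w)) + 1,
                    "symmetry": right / left if left > 0 else np.inf,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "channel",
            "index",
            "time_s",
            "amplitude_ohm",
            "width_s",
            "n_points",
            "symmetry",
        ],
    )


# ---------------------------------------------------------------------------
# stage 4: pairing
# ---------------------------------------------------------------------------


def pair_and_measure(candidates: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Greedily pair channel-1 and channel-2 peaks into transit events.

    Candidate pairs (channel-1 peak, later channel-2 peak) within the pairing
    window are consumed greedily in order of increasing lag, so a single
    missed or spurious peak cannot cascade into mispairing a whole run of
    events; velocity is L/Δt.  Unpaired peaks become rejected events with
    reason "unmatched".  Event n_points spans the full transit: first
    half-maximum crossing on channel 1 to the last on channel 2.
    """
    fs = cfg.sampling_rate_sps
    l_sep = cfg.pair_separation_um * 1e-6
    c1 = candidates[candidates["channel"] == 1].sort_values("time_s").reset_index(drop=True)
    c2 = candidates[candidates["channel"] == 2].sort_values("time_s").reset_index(drop=True)
    t1 = c1["time_s"].to_numpy(float)
    t2 = c2["time_s"].to_numpy(float)
    # lags far below L / v_max are physically impossible (the transit could
    # not yield the minimum point count); exclude them so a spurious peak at
    # near-zero lag cannot steal a pairing.  The factor 1/2 leaves the
    # implausibility judgement itself to the classification stage.
    dt_min = 0.5 * l_sep / max_detectable_velocity(cfg)
    lag = t2[None, :] - t1[:, None]
    ii, jj = np.nonzero((lag >= dt_min) & (lag <= cfg.max_lag_s))
    order = np.argsort(lag[ii, jj], kind="stable")
    used1 = np.zeros(len(c1), dtype=bool)
    used2 = np.zeros(len(c2), dtype=bool)
    matches: list[tuple[int, int]] = []
    for i, j in zip(ii[order], jj[order]):
        if not used1[i] and not used2[j]:
            used1[i] = used2[j] = True
            matches.append((i, j))
    rows = []
    for i, j in sorted(matches):
        p1 = c1.iloc[i]
        p2 = c2.iloc[j]
        dt = float(p2["time_s"] - p1["time_s"])
        span_s = (p2["time_s"] + p2["width_s"] / 2) - (p1["time_s"] - p1["width_s"] / 2)
        rows.append(
            {
                "t1_s": float(p1["time_s"]),
                "t2_s": float(p2["time_s"]),
                "dz1_ohm": float(p1["amplitude_ohm"]),
                "dz2_ohm": float(p2["amplitude_ohm"]),
                "dt_s": dt,
                "velocity_mps": l_sep / dt,
                "n_points": int(round(span_s * fs)) + 1,
                "width1_s": float(p1["width_s"]),
                "width2_s": float(p2["width_s"]),
                "symmetry1": float(p1["symmetry"]),
                "symmetry2": float(p2["symmetry"]),
                "paired": True,
                "label": "",
                "reject_reasons": "",
            }
        )
    for i in np.flatnonzero(~used1):
        rows.append(_unmatched_row(c1.iloc[i], 1))
    for j in np.flatnonzero(~used2):
        rows.append(_unmatched_row(c2.iloc[j], 2))
    cols = [
        "t1_s",
        "t2_s",
        "dz1_ohm",
        "dz2_ohm",
        "dt_s",
        "velocity_mps",
        "n_points",
        "width1_s",
        "width2_s",
        "symmetry1",
        "symmetry2",
        "paired",
        "label",
        "reject_reasons",
    ]
    events = pd.DataFrame(rows, columns=cols)
    return events.sort_values("t1_s", na_position="last").reset_index(drop=True)


def _unmatched_row(p: pd.Series, channel: int) -> dict:
    row = {
        "t1_s": float(p["time_s"]) if channel == 1 else np.nan,
        "t2_s": float(p["time_s"]) if channel == 2 else np.nan,
        "dz1_ohm": float(p["amplitude_ohm"]) if channel == 1 else np.nan,
        "dz2_ohm": float(p["amplitude_ohm"]) if channel == 2 else np.nan,
        "dt_s": np.nan,
        "velocity_mps": np.nan,
        "n_points": int(p["n_points"]),
        "width1_s": float(p["width_s"]) if channel == 1 else np.nan,
        "width2_s": float(p["width_s"]) if channel == 2 else np.nan,
        "symmetry1": float(p["symmetry"]) if channel == 1 else np.nan,
        "symmetry2": float(p["symmetry"]) if channel == 2 else np.nan,
        "paired": False,
        "label": "rejected",
        "reject_reasons": "unmatched",
    }
    return row


# ---------------------------------------------------------------------------
# stage 5: weak-supervision style classification
# ---------------------------------------------------------------------------


def lf_min_points(ev: pd.Series, cfg: PipelineConfig) -> int:
    """Reject transits with fewer samples than the minimum full-particle count."""
    return -1 if ev["n_points"] < cfg.min_points else 0


def lf_min_amplitude(ev: pd.Series, cfg: PipelineConfig) -> int:
    """Reject events below the ohm-equivalent of the minimum reportable size."""
    return -1 if ev["dz1_ohm"] + ev["dz2_ohm"] < cfg.min_amplitude_ohm else 0


def lf_lag_bounds(ev: pd.Series, cfg: PipelineConfig) -> int:
    """Reject cross-channel lags outside the physically possible velocity band."""
    dt_min = cfg.pair_separation_um * 1e-6 / max_detectable_velocity(cfg)
    dt_max = cfg.pair_separation_um * 1e-6 / cfg.min_velocity_mps
    return -1 if not dt_min <= ev["dt_s"] <= dt_max else 0


def lf_width_velocity(ev: pd.Series, cfg: PipelineConfig) -> int:
    """Reject pulses whose width disagrees with the span/velocity expectation."""
    if not np.isfinite(ev["velocity_mps"]):
        return 0
    expected = cfg.electrode_span_um * 1e-6 / ev["velocity_mps"]
    ratio = 0.5 * (ev["width1_s"] + ev["width2_s"]) / expected
    lo, hi = cfg.width_consistency_band
    return -1 if not lo <= ratio <= hi else 0


def lf_symmetry(ev: pd.Series, cfg: PipelineConfig) -> int:
    """Reject strongly asymmetric pulses (bubble-like tails)."""
    for s in (ev["symmetry1"], ev["symmetry2"]):
        if not np.isfinite(s) or max(s, 1.0 / s) > cfg.symmetry_limit:
            return -1
    return 0


def lf_beadlike(ev: pd.Series, cfg: PipelineConfig) -> int:
    """Positive evidence: every shape check passes at once."""
    checks = (lf_min_points, lf_min_amplitude, lf_lag_bounds, lf_width_velocity, lf_symmetry)
    return 1 if all(f(ev, cfg) == 0 for f in checks) else 0


DEFAULT_LABELING_FUNCTIONS = {
    "too_few_points": lf_min_points,
    "below_min_size": lf_min_amplitude,
    "implausible_lag": lf_lag_bounds,
    "width_velocity_mismatch": lf_width_velocity,
    "asymmetric": lf_symmetry,
    "beadlike": lf_beadlike,
}


def classify_events(
    events: pd.DataFrame,
    cfg: PipelineConfig,
    labeling_functions: dict | None = None,
) -> pd.DataFrame:
    """Label each paired event by majority vote of the labeling functions.

    Each function returns +1 (accept), −1 (reject) or 0 (abstain); an event
    is accepted when accepts outnumber rejects.  Rejection reasons record the
    names of the functions that voted against.  Unpaired events keep their
    "unmatched" rejection.
    """
    if labeling_functions is None:
        labeling_functions = DEFAULT_LABELING_FUNCTIONS
    if not labeling_functions:
        raise ValueError("no labeling functions configured")
    out = events.copy()
    labels, reasons, n_acc, n_rej = [], [], [], []
    for _, ev in out.iterrows():
        if not ev["paired"]:
            labels.append("rejected")
            reasons.append(ev["reject_reasons"] or "unmatched")
            n_acc.append(0)
            n_rej.append(1)
            continue
        votes = {name: int(fn(ev, cfg)) for name, fn in labeling_functions.items()}
        accepts = sum(v == 1 for v in votes.values())
        rejects = sum(v == -1 for v in votes.values())
        why = ";".join(name for name, v in votes.items() if v == -1)
        labels.append("accepted" if accepts > rejects else "rejected")
        reasons.append(why if accepts <= rejects else "")
        n_acc.append(accepts)
        n_rej.append(rejects)
    out["label"] = labels
    out["reject_reasons"] = reasons
    out["votes_accept"] = n_acc
    out["votes_reject"] = n_rej
    return out


# ---------------------------------------------------------------------------
# stage 6: sizing
# ---------------------------------------------------------------------------


def estimate_diameter(dz1_ohm: float, dz2_ohm: float, cal: SizingCalibration) -> float:
    """D = G·(|ΔZ1| + |ΔZ2|)^(1/3), micrometers (report to 0.1 µm)."""
    total = abs(dz1_ohm) + abs(dz2_ohm)
    if total <= 0:
        raise ValueError("zero summed impedance difference")
    return cal.g * total ** (1.0 / 3.0)


def calibrate_g(
    dz_sums_ohm: np.ndarray, known_diameters_um: np.ndarray
) -> SizingCalibration:
    """Fit G by least squares of D against (ΔZ1+ΔZ2)^(1/3) through the origin."""
    s = np.asarray(dz_sums_ohm, dtype=float) ** (1.0 / 3.0)
    d = np.asarray(known_diameters_um, dtype=float)
    if s.size == 0 or s.shape != d.shape:
        raise ValueError("need matching, non-empty reference arrays")
    if np.any(s <= 0) or np.any(d <= 0):
        raise ValueError("degenerate reference events (non-positive signal)")
    g = float(np.dot(d, s) / np.dot(s, s))
    residual = float(np.sqrt(np.mean((d - g * s) ** 2)))
    return SizingCalibration(g, residual, tuple(np.unique(np.round(d, 3))))


def add_diameters(events: pd.DataFrame, cal: SizingCalibration) -> pd.DataFrame:
    out = events.copy()
    total = out["dz1_ohm"].fillna(0.0).abs() + out["dz2_ohm"].fillna(0.0).abs()
    with np.errstate(invalid="ignore"):
        d = cal.g * np.cbrt(total.to_numpy(float))
    out["diameter_um"] = np.round(d, 1)  # reported to 0.1 µm
    return out


def population_histogram(
    events: pd.DataFrame,
    bin_width_um: float = 2.0,
    min_diameter_um: float = 45.0,
) -> tuple[pd.DataFrame, dict]:
    """Diameter histogram of accepted events plus summary statistics.

    Only accepted events at or above the minimum reportable size are counted.
    An empty accepted set yields an empty table with an explicit zero count.
    """
    acc = events[(events.get("label") == "accepted")] if "label" in events else events
    d = acc["diameter_um"].to_numpy(float) if "diameter_um" in acc else np.array([])
    d = d[np.isfinite(d) & (d >= min_diameter_um)]
    if d.size == 0:
        return (
            pd.DataFrame(columns=["bin_left_um", "bin_right_um", "count"]),
            {"count": 0, "median_um": np.nan, "iqr_um": np.nan, "min_um": np.nan, "max_um": np.nan},
        )
    lo = np.floor(d.min() / bin_width_um) * bin_width_um
    hi = np.ceil(d.max() / bin_width_um) * bin_width_um
    edges = np.arange(lo, hi + bin_width_um, bin_width_um)
    counts, edges = np.histogram(d, bins=edges)
    table = pd.DataFrame(
        {"bin_left_um": edges[:-1], "bin_right_um": edges[1:], "count": counts}
    )
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    summary = {
        "count": int(d.size),
        "median_um": float(med),
        "iqr_um": float(q3 - q1),
        "min_um": float(d.min()),
        "max_um": float(d.max()),
    }
    return table, summary


# ---------------------------------------------------------------------------
# end to end
# ---------------------------------------------------------------------------


def run_pipeline(
    stream: pd.DataFrame,
    cfg: PipelineConfig,
    cal: SizingCalibration | None = None,
) -> pd.DataFrame:
    """Full chain: condition → detect → pair → classify → size.

    Deterministic given the stream and configuration.  Stage counts are
    logged in the "accepted N of M detection events" style.
    """
    conditioned = denoise_and_smooth(remove_baseline(stream, cfg), cfg)
    candidates = detect_peaks(conditioned, cfg)
    events = classify_events(pair_and_measure(candidates, cfg), cfg)
    if cal is None:
        cal = SizingCalibration(cfg.sizing_constant_g)
    events = add_diameters(events, cal)
    n_acc = int((events["label"] == "accepted").sum())
    logger.info(
        "detected %d candidate peaks; %d events; accepted %d of %d detection events (%s)",
        len(candidates),
        len(events),
        n_acc,
        len(events),
        ", ".join(
            f"{k}: {v}"
            for k, v in events.loc[events["label"] == "rejected", "reject_reasons"]
            .str.split(";")
            .explode()
            .value_counts()
            .items()
        )
        or "none rejected",
    )
    return events
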