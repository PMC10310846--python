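"""Calibration and square-to-sine spectroscopy correction.

Raw PSD sweeps are contaminated twice: by frequency-dependent parasitics of
the analog chain (TIA roll-off, coupling) and by the odd harmonics of the
square excitation that the square-reference mixers fold down to DC.  The two
effects are removed in two stages:

1. *Calibration* — sweeps of known resistors give per-frequency complex
   factors (ideal parasitic-free reading / observed reading).  Because the
   parasitics are properties of the electronics alone, the same factors
   linearize every subsequent sweep.

2. *Square-to-sine correction* — from the calibrated in-phase reading at f0,
   the 1/n²-weighted readings at each odd harmonic frequency n·f0 that lies
   inside the measured grid are subtracted (analogously for the quadrature
   reading, with the alternating harmonic signs of the quadrature reference).
   Harmonics above the grid cannot be measured; their weight is reported in
   the residual flag and, by default, the reconstruction renormalises under
   the assumption that the spectrum is flat beyond the grid (exact for
   resistive samples, and the reason the instrument stays accurate at the top
   of its band where no harmonic is observable).

The corrected in-phase/quadrature pair maps back to polar impedance via
|Z| = K·V0·Rf / √(re² + im²) and θ = −atan2(im, re), with θ in the circuit
convention (capacitive → negative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .psd import (
    ExcitationConfig,
    harmonic_numbers,
    psd_dc_analytic,
    quadrature_signs,
)

__all__ = [
    "CalibrationTable",
    "build_calibration",
    "apply_calibration",
    "square_to_sine",
    "reconstruct_polar",
]


class StageError(ValueError):
    """Raised when a sweep is passed to a stage out of order."""


@dataclass(frozen=True)
class CalibrationTable:
    """Per-frequency complex correction factors from known-resistor sweeps."""

    frequencies: np.ndarray
    factors: np.ndarray
    reference_ohms: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        c = np.asarray(self.factors, dtype=complex)
        if f.ndim != 1 or f.size == 0 or c.shape != f.shape:
            raise ValueError("frequencies and factors must be matching 1-D arrays")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(~np.isfinite(c)) or np.any(c == 0):
            raise ValueError("factors must be finite and non-zero")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "factors", c)

    def factor_at(self, frequencies: np.ndarray) -> np.ndarray:
        """Log-frequency linear interpolation of the complex factors."""
        logf = np.log(np.asarray(frequencies, dtype=float))
        grid = np.log(self.frequencies)
        re = np.interp(logf, grid, self.factors.real)
        im = np.interp(logf, grid, self.factors.imag)
        return re + 1j * im

    def to_json(self) -> str:
        return json.dumps(
            {
                "frequencies_hz": self.frequencies.tolist(),
                "factor_real": self.factors.real.tolist(),
                "factor_imag": self.factors.imag.tolist(),
                "reference_ohms": list(self.reference_ohms),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationTable":
        d = json.loads(text)
        return cls(
            np.asarray(d["frequencies_hz"], dtype=float),
            np.asarray(d["factor_real"]) + 1j * np.asarray(d["factor_imag"]),
            tuple(d.get("reference_ohms", ())),
        )


def _sweep_complex(sweep: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    s = sweep.sort_values("frequency_hz")
    return s["frequency_hz"].to_numpy(float), s["re_v"].to_numpy(float) + 1j * s[
        "im_v"
    ].to_numpy(float)


def build_calibration(
    reference_sweeps: list[tuple[float, pd.DataFrame]],
    cfg: ExcitationConfig,
) -> CalibrationTable:
    """Derive the look-up table from sweeps of known resistors.

    The ideal reading at each frequency is the parasitic-free square-chain
    output for the known resistance (harmonics included); the factor is
    ideal/observed.  Multiple reference resistors are averaged — for a linear
    chain the factors are independent of the reference value.
    """
    if not reference_sweeps:
        raise ValueError("at least one reference sweep required")
    clean_cfg = _dc_replace(cfg, cf=0.0, bandwidth_hz=None)
    grid = None
    factor_sets = []
    for ohms, sweep in reference_sweeps:
        if ohms <= 0:
            raise ValueError("reference resistance must be > 0")
        f, observed = _sweep_complex(sweep)
        # average duplicate channels onto one grid
        tmp = pd.DataFrame({"f": f, "v": observed}).groupby("f", as_index=False).mean()
        f, observed = tmp["f"].to_numpy(float), tmp["v"].to_numpy(complex)
        if grid is None:
            grid = f
        elif f.shape != grid.shape or not np.allclose(f, grid, rtol=1e-12):
            raise ValueError("reference sweeps must share one frequency grid")
        if np.any(observed == 0):
            raise ValueError("zero observed reading in reference sweep")
        ideal = np.array(
            [
                complex(
                    psd_dc_analytic(clean_cfg.at(fi), [ohms] * cfg.n_harmonics).re_v, 0.0
                )
                for fi in grid
            ]
        )
        factor_sets.append(ideal / observed)
    factors = np.mean(factor_sets, axis=0)
    return CalibrationTable(grid, factors, tuple(r for r, _ in reference_sweeps))


def apply_calibration(sweep: pd.DataFrame, table: CalibrationTable) -> pd.DataFrame:
    """Multiply raw readings by the calibration factors (stage raw → calibrated)."""
    if "stage" in sweep.columns and (sweep["stage"] != "raw").any():
        raise StageError("calibration expects a raw sweep")
    out = sweep.copy()
    factor = table.factor_at(out["frequency_hz"].to_numpy(float))
    v = (out["re_v"].to_numpy(float) + 1j * out["im_v"].to_numpy(float)) * factor
    out["re_v"], out["im_v"] = v.real, v.imag
    out["stage"] = "calibrated"
    return out


def identity_calibration(frequencies: np.ndarray) -> CalibrationTable:
    f = np.sort(np.unique(np.asarray(frequencies, dtype=float)))
    return CalibrationTable(f, np.ones_like(f, dtype=complex))


def reconstruct_polar(
    re_v: float, im_v: float, cfg: ExcitationConfig
) -> tuple[float, float]:
    """Map a sine-equivalent PSD pair to (|Z| ohms, θ radians).

    |Z| = K·V0·Rf/√(re²+im²); θ = −atan2(im, re) so that a capacitive sample
    (positive quadrature reading) comes out with negative phase.
    """
    amp = np.hypot(re_v, im_v)
    if amp == 0:
        raise ValueError("zero reading: phase undefined")
    return cfg.k_psd * cfg.v0 * cfg.rf / amp, -np.arctan2(im_v, re_v)


def square_to_sine(
    sweep: pd.DataFrame,
    cfg: ExcitationConfig,
    mode: str = "recursive",
    assume_flat_above_grid: bool = True,
) -> pd.DataFrame:
    """Remove odd-harmonic contamination from a calibrated sweep.

    Parameters
    ----------
    sweep
        Calibrated sweep over a contiguous logarithmic grid (columns
        frequency_hz, channel, re_v, im_v, stage == "calibrated").
    mode
        "literal" subtracts the raw (calibrated) harmonic readings as the
        correction equation is usually written; "recursive" processes the grid
        from the highest frequency down and subtracts already-corrected values
        where available, removing second-order contamination.
    assume_flat_above_grid
        Harmonic frequencies above the grid cannot be measured and are never
        subtracted (their weight is reported in ``residual_flag``).  When this
        flag is set (default) the reconstruction divides by the weight of the
        measurable terms only, which is exact if the spectrum is flat beyond
        the grid; when unset the omitted weight is simply dropped.

    Returns the corrected sweep with added columns z_mag_ohm, z_phase_deg and
    residual_flag (0 = every harmonic was measurable, 1 = none was).
    """
    if mode not in ("literal", "recursive"):
        raise ValueError("mode must be 'literal' or 'recursive'")
    if "stage" not in sweep.columns or (sweep["stage"] != "calibrated").any():
        raise StageError("square_to_sine expects a calibrated sweep")
    n_all = harmonic_numbers(cfg)
    n_sub = n_all[1:]  # harmonics 3, 5, ... are the contamination
    s_sub = quadrature_signs(n_sub)
    weight_total = float(np.sum(1.0 / n_sub.astype(float) ** 2))
    scale = cfg.k_psd * cfg.v0 * cfg.rf

    frames = []
    for ch, grp in sweep.groupby("channel"):
        grp = grp.sort_values("frequency_hz").reset_index(drop=True)
        f = grp["frequency_hz"].to_numpy(float)
        u_re = grp["re_v"].to_numpy(float) / scale
        u_im = grp["im_v"].to_numpy(float) / scale
        f_max = f[-1] * (1.0 + 1e-9)
        logf = np.log(f)
        x_re = np.full_like(u_re, np.nan)
        x_im = np.full_like(u_im, np.nan)
        residual = np.zeros_like(u_re)
        for i in range(len(f) - 1, -1, -1):
            fh = n_sub * f[i]
            in_grid = fh <= f_max
            sub_re = 0.0
            sub_im = 0.0
            if np.any(in_grid):
                logfh = np.log(fh[in_grid])
                if mode == "literal":
                    vr = np.interp(logfh, logf, u_re)
                    vi = np.interp(logfh, logf, u_im)
                else:
                    known = ~np.isnan(x_re)
                    # corrected values exist at all grid points above f[i];
                    # fall back to raw readings if the grid is too sparse for
                    # the lowest harmonic to be bracketed by corrected points
                    if np.any(known) and logfh.min() >= logf[known].min():
                        vr = np.interp(logfh, logf[known], x_re[known])
                        vi = np.interp(logfh, logf[known], x_im[known])
                    else:
                        vr = np.interp(logfh, logf, u_re)
                        vi = np.interp(logfh, logf, u_im)
                w = 1.0 / n_sub[in_grid].astype(float) ** 2
                sub_re = float(np.sum(w * vr))
                sub_im = float(np.sum(w * s_sub[in_grid] * vi))
            w_out = 1.0 / n_sub[~in_grid].astype(float) ** 2
            residual[i] = float(np.sum(w_out)) / weight_total
            if assume_flat_above_grid:
                norm_re = 1.0 + float(np.sum(w_out))
                norm_im = 1.0 + float(np.sum(s_sub[~in_grid] * w_out))
            else:
                norm_re = norm_im = 1.0
            x_re[i] = (u_re[i] - sub_re) / norm_re
            x_im[i] = (u_im[i] - sub_im) / norm_im
        out = grp.copy()
        out["re_v"] = x_re * scale
        out["im_v"] = x_im * scale
        amp = np.hypot(x_re, x_im)
        with np.errstate(divide="ignore"):
            out["z_mag_ohm"] = np.where(amp > 0, 1.0 / amp, np.inf)
        out["z_phase_deg"] = np.degrees(-np.arctan2(x_im, x_re))
        out["residual_flag"] = residual
        out["stage"] = "corrected"
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
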