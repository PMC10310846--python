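"""Lumped-element impedance models.

A circuit is a tree of resistors and capacitors combined in series or in
parallel.  Evaluating the tree at an angular frequency gives the complex
impedance ``Z = |Z| e^{jθ}`` with ``θ = atan2(Im Z, Re Z)``, so a capacitive
network has negative phase.  These models provide the ground-truth spectra
against which the square-wave measurement chain is simulated and validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircuitModel",
    "resistor",
    "capacitor",
    "series",
    "parallel",
    "validation_circuit",
    "validation_circuit_alt",
    "spectrum_frame",
]


class CircuitConfigError(ValueError):
    """Raised for malformed circuit descriptions."""


@dataclass(frozen=True)
class CircuitModel:
    """A node in a series/parallel tree of resistors and capacitors.

    Parameters
    ----------
    kind
        One of ``"resistor"``, ``"capacitor"``, ``"series"``, ``"parallel"``.
    value
        Ohms for a resistor, farads for a capacitor; unused for composites.
    children
        Sub-circuits for ``series`` / ``parallel`` nodes.
    """

    kind: str
    value: float = 0.0
    children: tuple["CircuitModel", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind in ("resistor", "capacitor"):
            if not np.isfinite(self.value) or self.value <= 0:
                raise CircuitConfigError(
                    f"{self.kind} value must be finite and > 0, got {self.value!r}"
                )
            if self.children:
                raise CircuitConfigError(f"{self.kind} cannot have children")
        elif self.kind in ("series", "parallel"):
            if not self.children:
                raise CircuitConfigError(f"empty {self.kind} combination")
        else:
            raise CircuitConfigError(f"unknown element kind {self.kind!r}")

    # -- evaluation ---------------------------------------------------------

    def impedance(self, frequencies: Iterable[float] | float) -> np.ndarray:
        """Complex impedance at each frequency (Hz).

        Series nodes sum child impedances; parallel nodes sum admittances.
        A capacitor contributes ``1/(jωC)``.
        """
        f = np.atleast_1d(np.asarray(frequencies, dtype=float))
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("frequencies must be finite and > 0")
        return self._z(2.0 * np.pi * f)

    def _z(self, omega: np.ndarray) -> np.ndarray:
        if self.kind == "resistor":
            return np.full(omega.shape, self.value, dtype=complex)
        if self.kind == "capacitor":
            return 1.0 / (1j * omega * self.value)
        child_z = [c._z(omega) for c in self.children]
        if self.kind == "series":
            return np.sum(child_z, axis=0)
        return 1.0 / np.sum([1.0 / z for z in child_z], axis=0)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        if self.kind == "resistor":
            return {"resistor": self.value}
        if self.kind == "capacitor":
            return {"capacitor": self.value}
        return {self.kind: [c.to_dict() for c in self.children]}

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "CircuitModel":
        """Build a circuit from a nested ``{series|parallel|resistor|capacitor: ...}`` mapping."""
        if not isinstance(mapping, Mapping) or len(mapping) != 1:
            raise CircuitConfigError(f"expected a single-key mapping, got {mapping!r}")
        (kind, payload), = mapping.items()
        if kind in ("resistor", "capacitor"):
            return cls(kind, float(payload))
        if kind in ("series", "parallel"):
            if not isinstance(payload, Sequence):
                raise CircuitConfigError(f"{kind} requires a list of children")
            return cls(kind, children=tuple(cls.from_dict(c) for c in payload))
        raise CircuitConfigError(f"unknown element kind {kind!r}")

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "CircuitModel":
        return cls.from_dict(json.loads(text))


def resistor(ohms: float) -> CircuitModel:
    return CircuitModel("resistor", ohms)


def capacitor(farads: float) -> CircuitModel:
    return CircuitModel("capacitor", farads)


def series(*children: CircuitModel) -> CircuitModel:
    return CircuitModel("series", children=tuple(children))


def parallel(*children: CircuitModel) -> CircuitModel:
    return CircuitModel("parallel", children=tuple(children))


def validation_circuit() -> CircuitModel:
    """Reference validation circuit: 10 kΩ in series with (4.7 kΩ ∥ 100 pF)."""
    return series(resistor(10e3), parallel(resistor(4.7e3), capacitor(100e-12)))


def validation_circuit_alt() -> CircuitModel:
    """Variant with a 4.47 kΩ parallel resistor (alternative reported value)."""
    return series(resistor(10e3), parallel(resistor(4.47e3), capacitor(100e-12)))


def spectrum_frame(model: CircuitModel, frequencies: Iterable[float]) -> pd.DataFrame:
    """Tabulate Z(f) with columns frequency_hz, z_real_ohm, z_imag_ohm, z_mag_ohm, z_phase_deg."""
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    z = model.impedance(f)
    return pd.DataFrame(
        {
            "frequency_hz": f,
            "z_real_ohm": z.real,
            "z_imag_ohm": z.imag,
            "z_mag_ohm": np.abs(z),
            "z_phase_deg": np.degrees(np.angle(z)),
        }
    )
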