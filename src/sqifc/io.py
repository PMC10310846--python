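"""CSV/JSON/YAML I/O with provenance headers.

All tabular outputs are plain CSV with ``#``-prefixed header lines recording
the package version, the seed and a hash of the configuration, so any output
file documents how to regenerate itself.  Floats are written with 17
significant digits (lossless round-trip well beyond the 12 digits required).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__

__all__ = [
    "config_hash",
    "load_config",
    "save_config",
    "write_table",
    "read_table",
]


def config_hash(config: Mapping | None) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def save_config(config: Mapping, path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(dict(config), indent=2, default=str))
    else:
        p.write_text(yaml.safe_dump(dict(config), sort_keys=True))


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
    comment: str | None = None,
) -> None:
    """Write a CSV with provenance header lines (version, seed, config hash)."""
    lines = [f"# sqifc {__version__}"]
    lines.append(f"# seed: {seed if seed is not None else 'none'}")
    lines.append(f"# config_hash: {config_hash(config)}")
    if comment:
        lines.append(f"# {comment}")
    body = df.to_csv(index=False, float_format="%.17g")
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (``#`` lines are skipped)."""
    return pd.read_csv(path, comment="#")
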