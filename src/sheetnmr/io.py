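"""File formats, run configuration and provenance.

Formats:

* Dephasing curves — CSV with columns ``time_s,value`` and ``#``-prefixed
  header comments recording the sequence kind, MAS rate and convention.
* Spectra — CSV with columns ``wavenumber_cm-1,absorbance``.
* Spin systems — JSON (site_id, isotope, xyz, optional csa).
* Results — JSON with a provenance block (input hashes, parameters, seed,
  package version) so a result bundle can be regenerated from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curves import DephasingCurve
from .ftir import Spectrum
from .geometry import SpinSystem

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_spin_system_json",
    "read_spin_system_json",
    "write_results_json",
    "make_manifest",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid run configuration; message carries the offending field."""


def write_curve_csv(curve: DephasingCurve, path, metadata: dict | None = None) -> None:
    path = Path(path)
    lines = [f"# convention: {curve.convention}"]
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append("time_s,value")
    for t, v in zip(curve.times, curve.values):
        lines.append(f"{float(t)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_curve_csv(path, strict: bool | None = None) -> DephasingCurve:
    path = Path(path)
    convention = "delta_S_over_S0"
    for line in path.read_text().splitlines():
        if line.startswith("#") and "convention:" in line:
            convention = line.split("convention:")[1].strip()
    df = pd.read_csv(path, comment="#")
    if strict is None:
        strict = False
    return DephasingCurve(
        df["time_s"].to_numpy(), df["value"].to_numpy(), convention, strict=strict
    )


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm-1": spectrum.wavenumber, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)


def read_spectrum_csv(path) -> Spectrum:
    df = pd.read_csv(path, comment="#")
    return Spectrum(df["wavenumber_cm-1"].to_numpy(), df["absorbance"].to_numpy())


def write_spin_system_json(system: SpinSystem, path) -> None:
    Path(path).write_text(json.dumps(system.to_dict(), indent=2) + "\n")


def read_spin_system_json(path) -> SpinSystem:
    return SpinSystem.from_dict(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_manifest(
    inputs: dict[str, str | Path],
    parameters: dict,
    seed: int | None = None,
) -> dict:
    """Provenance block: hashed inputs, parameters, seed and version."""
    return {
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
        },
        "parameters": _jsonable(parameters),
        "seed": seed,
        "version": __version__,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_results_json(results: dict, path, manifest: dict | None = None) -> None:
    payload = _jsonable(dict(results))
    if manifest is not None:
        payload["provenance"] = manifest
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


_COMMANDS = ("build", "simulate", "fit", "betaindex", "fixtures")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline invocation."""

    command: str
    inputs: dict[str, str] = field(default_factory=dict)
    output_dir: str = "."
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.command not in _COMMANDS:
            raise ConfigError(f"command: unknown command {self.command!r}")
        for name, p in self.inputs.items():
            if not Path(p).exists():
                raise ConfigError(f"inputs.{name}: path does not exist: {p}")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"log_level: invalid level {self.log_level!r}")
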