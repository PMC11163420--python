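"""Synthetic data generators.

Everything the analysis pipeline consumes can be generated here without
any instrument data: canonical linear spin systems, noisy mixture
dephasing curves (a convex combination of simulated basis curves plus a
non-dephasing remainder, with i.i.d. Gaussian noise), and amide-I FTIR
spectra built from Gaussian bands on a polynomial baseline.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import DephasingCurve
from .ftir import Spectrum
from .geometry import CSAParameters, SpinSystem, build_linear_spin_array

__all__ = [
    "SyntheticCurveSpec",
    "make_canonical_systems",
    "generate_noisy_curve",
    "generate_amide_spectrum",
    "DEFAULT_TIME_GRID",
]

#: default recoupling-time grid mirroring the experiments: 16 points,
#: 0 to 61.44 ms (snapped to the rotor grid by the simulators as needed)
DEFAULT_TIME_GRID = np.linspace(0.0, 61.44e-3, 16)

#: the carbonyl CSA used for PITHIRDS simulations
CARBONYL_CSA = CSAParameters(aniso_ppm=-75.0, asymmetry=0.75)


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for one noisy synthetic dephasing curve."""

    true_fractions: tuple[float, ...]
    basis_names: tuple[str, ...]
    noise_sigma: float = 0.02
    time_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TIME_GRID.copy())
    seed: int = 0

    def __post_init__(self):
        f = tuple(float(v) for v in self.true_fractions)
        if any(v < 0 or v > 1 for v in f) or sum(f) > 1.0 + 1e-12:
            raise ValueError("fractions must be in [0,1] and sum to at most 1")
        if len(f) != len(self.basis_names):
            raise ValueError("one fraction per basis name required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        object.__setattr__(self, "true_fractions", f)
        object.__setattr__(self, "basis_names", tuple(self.basis_names))
        object.__setattr__(
            self, "time_grid", np.asarray(self.time_grid, dtype=float)
        )


def make_canonical_systems() -> dict[str, SpinSystem]:
    """The six canonical linear arrays used throughout the pipeline.

    * ``pithirds_8C_4A`` / ``pithirds_8C_5A`` — eight 13C at 4/5 A with
      the carbonyl CSA, for 13C-13C recoupling;
    * ``redor_4C4N_4A`` / ``redor_4C4N_5A`` — eight-spin alternating
      13C/15N arrays at 4/5 A, for REDOR;
    * ``pair_CN_4A`` / ``pair_CN_5A`` — isolated 13C-15N pairs, the
      fsREDOR / two-spin reference geometries.
    """
    out = {}
    for dist in (4.0, 5.0):
        tag = f"{dist:.0f}A"
        out[f"pithirds_8C_{tag}"] = build_linear_spin_array(
            8, dist, ["C13"], csa=CARBONYL_CSA, name=f"pithirds_8C_{tag}"
        )
        out[f"redor_4C4N_{tag}"] = build_linear_spin_array(
            8, dist, ["C13", "N15"], name=f"redor_4C4N_{tag}"
        )
        out[f"pair_CN_{tag}"] = build_linear_spin_array(
            2, dist, ["C13", "N15"], name=f"pair_CN_{tag}"
        )
    return out


def generate_noisy_curve(
    spec: SyntheticCurveSpec, bases: dict[str, DephasingCurve]
) -> DephasingCurve:
    """Noisy convex mixture of basis curves on the spec's time grid.

    value(t) = sum_i p_i * basis_i(t) + eps_t with eps_t ~ N(0, sigma^2),
    in the Delta S/S0 convention (the implicit remainder is the flat zero
    line of uncoupled spins).  Deterministic for a fixed seed.
    """
    missing = [n for n in spec.basis_names if n not in bases]
    if missing:
        raise KeyError(f"unknown basis curves: {missing}")
    t = spec.time_grid
    mix = np.zeros_like(t)
    for p, name in zip(spec.true_fractions, spec.basis_names):
        b = bases[name].as_delta()
        if len(b) != t.size or not np.allclose(b.times, t, rtol=0, atol=1e-12):
            raise ValueError(
                f"basis {name!r} is not sampled on the spec time grid; "
                "interpolate it first"
            )
        mix = mix + p * b.values
    rng = np.random.default_rng(spec.seed)
    noisy = mix + rng.normal(0.0, spec.noise_sigma, size=t.size)
    return DephasingCurve(t, noisy, "delta_S_over_S0", strict=spec.noise_sigma == 0)


def generate_amide_spectrum(
    band_params,
    baseline_coeffs=(),
    noise_sigma: float = 0.0,
    seed: int = 0,
    wavenumber_range: tuple[float, float] = (1500.0, 1800.0),
) -> Spectrum:
    """Synthetic amide-I spectrum: Gaussian bands + polynomial baseline + noise.

    ``band_params`` is a list of (center cm-1, sigma cm-1, amplitude)
    triples; centers must lie within 1500-1800 cm-1.  The spectrum is
    sampled on a 1 cm-1 grid and is deterministic per seed.
    """
    lo, hi = wavenumber_range
    x = np.arange(lo, hi + 0.5, 1.0)
    y = np.zeros_like(x)
    for center, sigma, amp in band_params:
        if not 1500.0 <= center <= 1800.0:
            raise ValueError(f"band center {center} outside 1500-1800 cm-1")
        if sigma <= 0:
            raise ValueError("band sigma must be positive")
        y += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    if len(baseline_coeffs):
        # coefficients in increasing order, argument centered mid-range
        y += np.polynomial.polynomial.polyval(x - 0.5 * (lo + hi), baseline_coeffs)
    if noise_sigma:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=x.size)
    return Spectrum(x, y)
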