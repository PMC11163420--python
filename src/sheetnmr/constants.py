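"""Physical constants and dipolar coupling strengths.

Gyromagnetic ratios are CODATA values.  The secular dipolar coupling
constant between two nuclei separated by r is

    d = mu0 * |gamma_a * gamma_b| * hbar / (8 * pi**2 * r**3)   [Hz]

which gives the familiar benchmarks d(13C,15N) ~ 48 Hz at 4 A and
d(13C,13C) ~ 61 Hz at 5 A.
"""

from __future__ import annotations

import numpy as np

MU0 = 1.25663706212e-6  # vacuum permeability, T^2 m^3 / J
HBAR = 1.054571817e-34  # reduced Planck constant, J s

#: gyromagnetic ratios, rad s^-1 T^-1
GAMMA = {
    "C13": 6.728284e7,
    "N15": -2.7126180e7,
    "H1": 2.6752218744e8,
}

#: isotopes this package simulates (all spin-1/2)
ISOTOPES = ("C13", "N15")

#: static field of the reference instrument (11.74 T, 500 MHz 1H)
B0_TESLA = 11.7440

MAGIC_ANGLE = float(np.arccos(1.0 / np.sqrt(3.0)))  # 54.7356... degrees in rad

#: fraction of carbon that is 13C without enrichment
NATURAL_ABUNDANCE_C13 = 0.011


def larmor_frequency(isotope: str, b0: float = B0_TESLA) -> float:
    """Larmor frequency magnitude in Hz at field ``b0`` (Tesla)."""
    return abs(GAMMA[isotope]) * b0 / (2.0 * np.pi)


def dipolar_coupling_constant(isotope_a: str, isotope_b: str, r_angstrom: float) -> float:
    """Secular dipolar coupling constant in Hz for two spins ``r_angstrom`` apart.

    Parameters
    ----------
    isotope_a, isotope_b:
        Isotope codes, e.g. ``"C13"`` or ``"N15"``.
    r_angstrom:
        Internuclear distance in Angstrom; must be positive.

    Returns
    -------
    float
        Magnitude of the coupling constant d in Hz; scales as r**-3.
    """
    if r_angstrom <= 0:
        raise ValueError(f"internuclear distance must be positive, got {r_angstrom}")
    ga = GAMMA[isotope_a]
    gb = GAMMA[isotope_b]
    r = r_angstrom * 1e-10
    b_rad = MU0 * abs(ga * gb) * HBAR / (4.0 * np.pi * r**3)
    return b_rad / (2.0 * np.pi)
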