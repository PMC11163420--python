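"""Shared fixtures.

The expensive powder-averaged simulations (the eight-spin REDOR basis and
the isolated-pair reference curves) are computed once per session and
shared between the unit tests, the mixture-recovery tests and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from sheetnmr.powder import powder_scheme
from sheetnmr.sequences import SequenceParams, redor_times, simulate_redor
from sheetnmr.synthetic import make_canonical_systems


@pytest.fixture(scope="session")
def canonical_systems():
    return make_canonical_systems()


@pytest.fixture(scope="session")
def redor_grid():
    """16-point rotor-synchronized REDOR grid, 0 to ~61.44 ms at 10 kHz."""
    return redor_times(10e3, 61.44e-3, 16)


@pytest.fixture(scope="session")
def redor_params(redor_grid):
    return SequenceParams("REDOR", 10e3, redor_grid)


@pytest.fixture(scope="session")
def powder377():
    return powder_scheme(377)


@pytest.fixture(scope="session")
def pair_4A_curve(canonical_systems, redor_params, powder377):
    """Two-spin 13C-15N REDOR curve at 4 A (the fsREDOR 100%-coupled basis)."""
    return simulate_redor(canonical_systems["pair_CN_4A"], redor_params, powder377)


@pytest.fixture(scope="session")
def pair_5A_curve(canonical_systems, redor_params, powder377):
    return simulate_redor(canonical_systems["pair_CN_5A"], redor_params, powder377)


@pytest.fixture(scope="session")
def redor_8spin_5A_curve(canonical_systems, redor_params, powder377):
    """Eight-spin alternating-array REDOR curve at 5 A (the antiparallel
    basis; also the plateau-height acceptance scenario)."""
    return simulate_redor(canonical_systems["redor_4C4N_5A"], redor_params, powder377)
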