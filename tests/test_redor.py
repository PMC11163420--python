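"""REDOR engine: analytic oracles, invariances and error handling.

The dipolar coupling constants asserted here were evaluated independently
from mu0 * |gamma_a gamma_b| * hbar / (8 pi^2 r^3) with CODATA
gyromagnetic ratios (gamma_C = 6.728284e7, gamma_N = -2.71262e7
rad s^-1 T^-1): 47.86 Hz for 13C-15N at 4.0 A and 60.78 Hz for 13C-13C
at 5.0 A.
"""

import numpy as np
import pytest

from sheetnmr.constants import dipolar_coupling_constant
from sheetnmr.engine import BinaryPower, product_of_steps
from sheetnmr.geometry import SpinSite, SpinSystem, build_linear_spin_array
from sheetnmr.powder import powder_scheme
from sheetnmr.sequences import (
    InvalidSelectionError,
    InvalidSystemError,
    SequenceParams,
    redor_product_of_cosines,
    redor_times,
    redor_universal_curve,
    simulate_fsredor,
    simulate_redor,
)


class TestDipolarConstant:
    def test_cn_at_4A(self):
        assert dipolar_coupling_constant("C13", "N15", 4.0) == pytest.approx(
            47.86, abs=0.05
        )

    def test_cc_at_5A(self):
        assert dipolar_coupling_constant("C13", "C13", 5.0) == pytest.approx(
            60.78, abs=0.05
        )

    def test_inverse_cube_law(self):
        d1 = dipolar_coupling_constant("C13", "N15", 3.0)
        d2 = dipolar_coupling_constant("C13", "N15", 6.0)
        assert d1 / d2 == pytest.approx(8.0, rel=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            dipolar_coupling_constant("C13", "N15", 0.0)


class TestUniversalCurve:
    def test_zero_at_zero(self):
        assert redor_universal_curve(48.0, 0, 1e-4) == 0.0

    def test_asymptote(self):
        # lambda >= 10: within 0.05 of complete dephasing
        val = redor_universal_curve(50.0, 2000, 1e-4)  # lambda = 10
        assert abs(val - 1.0) < 0.05

    def test_matches_brute_force_powder_quadrature(self):
        """Independent oracle: integrate the accumulated REDOR phase per
        rotor cycle over a fine (beta, gamma) quadrature and powder-average
        cos(n*phi); must match the Bessel closed form to 1e-3."""
        d_hz = 25.0
        tr = 1e-4
        n_cyc = 200  # lambda = 0.5
        b = 2 * np.pi * d_hz
        nb, ng, nt = 200, 64, 2000
        theta_m = np.arccos(1 / np.sqrt(3))
        t = (np.arange(nt) + 0.5) * (tr / nt)
        sign = np.where(t < tr / 2, 1.0, -1.0)
        nodes, wts = np.polynomial.legendre.leggauss(nb)
        beta = np.arccos(nodes)
        gamma = 2 * np.pi * (np.arange(ng) + 0.5) / ng
        acc = 0.0
        wt_sum = 0.0
        for bb, wb in zip(beta, wts):
            # internuclear vector at polar angle bb, azimuth gamma in the
            # rotor frame; field direction per engine geometry
            ux = np.sin(bb) * np.cos(gamma)
            uy = np.sin(bb) * np.sin(gamma)
            uz = np.cos(bb)
            wt = np.cos(2 * np.pi * t[:, None] / tr)
            st = np.sin(2 * np.pi * t[:, None] / tr)
            cos_th = (
                np.cos(theta_m) * uz
                - np.sin(theta_m) * (ux * wt - uy * st)
            )
            f = 0.5 * (3 * cos_th**2 - 1)
            phi_cycle = b * np.sum(f * sign[:, None], axis=0) * (tr / nt)
            acc += wb * np.mean(np.cos(n_cyc * phi_cycle))
            wt_sum += wb
        oracle = 1.0 - acc / wt_sum
        closed = redor_universal_curve(d_hz, n_cyc, tr)
        assert abs(oracle - closed) < 1e-3


class TestRedorEngine:
    def test_pair_matches_universal_curve(self, canonical_systems, redor_params, powder377, pair_5A_curve):
        d = dipolar_coupling_constant("C13", "N15", 5.0)
        tr = redor_params.rotor_period
        ana = redor_universal_curve(d, pair_5A_curve.times / tr, tr)
        assert np.abs(pair_5A_curve.values - ana).max() < 0.02

    def test_single_carbon_flat_zero(self):
        sys = build_linear_spin_array(1, 5.0, ["C13"])
        times = redor_times(10e3, 20e-3, 5)
        curve = simulate_redor(sys, SequenceParams("REDOR", 10e3, times))
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_no_carbon_rejected(self):
        sys = build_linear_spin_array(2, 5.0, ["N15"])
        times = redor_times(10e3, 20e-3, 5)
        with pytest.raises(InvalidSystemError):
            simulate_redor(sys, SequenceParams("REDOR", 10e3, times))

    @pytest.mark.filterwarnings("ignore:REDOR dephasing outside")
    def test_product_of_cosines_oracle(self):
        """With no homonuclear couplings (single 13C, several 15N) the
        engine must match the commuting-limit product-of-cosines law.

        This three-nitrogen construction transiently overshoots complete
        dephasing (as the analytic law does), which trips the engine's
        range diagnostic; the check here is engine-oracle agreement."""
        sites = [
            SpinSite("c0", "C13", np.array([0.0, 0.0, 0.0])),
            SpinSite("n1", "N15", np.array([4.0, 0.0, 0.0])),
            SpinSite("n2", "N15", np.array([-2.0, 3.5, 0.0])),
            SpinSite("n3", "N15", np.array([1.0, -2.0, 4.5])),
        ]
        sys = SpinSystem(tuple(sites), "one_c_three_n")
        times = redor_times(10e3, 30e-3, 6)
        params = SequenceParams("REDOR", 10e3, times)
        pw = powder_scheme(144)
        engine = simulate_redor(sys, params, pw)
        oracle = redor_product_of_cosines(sys, params, pw, n_quad=2048)
        assert np.abs(engine.values - oracle.values).max() < 1e-3

    def test_nitrogen_relabeling_invariance(self):
        """Heteronuclear dephasing must not depend on 15N site order."""
        base = [
            SpinSite("c0", "C13", np.array([0.0, 0.0, 0.0])),
            SpinSite("na", "N15", np.array([4.0, 0.0, 0.0])),
            SpinSite("nb", "N15", np.array([0.0, 5.0, 0.0])),
        ]
        times = redor_times(10e3, 20e-3, 4)
        params = SequenceParams("REDOR", 10e3, times)
        pw = powder_scheme(89)
        c1 = simulate_redor(SpinSystem(tuple(base)), params, pw)
        swapped = (base[0], base[2], base[1])
        c2 = simulate_redor(SpinSystem(swapped), params, pw)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-10)

    def test_global_rotation_invariance(self):
        """The powder average is isotropic: rotating the whole spin system
        changes the curve only within powder-convergence tolerance."""
        from scipy.spatial.transform import Rotation

        sys = build_linear_spin_array(2, 5.0, ["C13", "N15"])
        rot = Rotation.from_euler("zyz", [0.3, 1.1, -0.7]).as_matrix()
        rotated = SpinSystem(
            tuple(
                SpinSite(s.site_id, s.isotope, rot @ s.position)
                for s in sys.sites
            ),
            "rotated",
        )
        times = redor_times(10e3, 40e-3, 6)
        params = SequenceParams("REDOR", 10e3, times)
        pw = powder_scheme(377)
        c1 = simulate_redor(sys, params, pw)
        c2 = simulate_redor(rotated, params, pw)
        assert np.abs(c1.values - c2.values).max() < 0.02

    def test_curve_convention_and_bounds(self, redor_8spin_5A_curve):
        curve = redor_8spin_5A_curve
        assert curve.convention == "delta_S_over_S0"
        assert curve.values[0] == 0.0
        assert np.all(curve.values >= -0.05) and np.all(curve.values <= 1.05)

    def test_times_must_be_rotor_synchronized(self):
        sys = build_linear_spin_array(2, 5.0, ["C13", "N15"])
        params = SequenceParams("REDOR", 10e3, np.array([0.0, 1.23e-3]))
        with pytest.raises(ValueError, match="rotor"):
            simulate_redor(sys, params, powder_scheme(8))


class TestPropagatorCaching:
    def test_binary_power_matches_sequential_product(self):
        """Cached rotor-period powers must be bit-identical to step-by-step
        multiplication of the same propagator."""
        rng = np.random.default_rng(7)
        h = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        h = h + h.conj().T
        from scipy.linalg import expm

        u = expm(-1j * h * 0.01)[None]
        bp = BinaryPower(u, 13)
        seq = np.eye(4, dtype=complex)[None]
        for n in range(14):
            if n:
                seq = u @ seq
            got = bp.power(n)
            np.testing.assert_allclose(got, seq, atol=1e-12)


class TestFsRedor:
    def test_equals_reduced_pair_redor(self, canonical_systems, redor_params, powder377):
        sys8 = canonical_systems["redor_4C4N_4A"]
        params = SequenceParams(
            "fsREDOR",
            10e3,
            redor_params.recoupling_times,
            selected_pair=("s0", "s1"),
        )
        fs = simulate_fsredor(sys8, params, powder377)
        pair = sys8.select(["s0", "s1"])
        direct = simulate_redor(pair, params, powder377)
        np.testing.assert_array_equal(fs.values, direct.values)

    def test_distant_pair_is_flat(self):
        sys = build_linear_spin_array(2, 50.0, ["C13", "N15"])
        times = redor_times(10e3, 40e-3, 5)
        params = SequenceParams(
            "fsREDOR", 10e3, times, selected_pair=("s0", "s1")
        )
        curve = simulate_fsredor(sys, params, powder_scheme(34))
        assert np.abs(curve.values).max() < 1e-3

    def test_selection_errors(self, canonical_systems):
        sys8 = canonical_systems["redor_4C4N_4A"]
        times = redor_times(10e3, 20e-3, 3)
        with pytest.raises(InvalidSelectionError):
            simulate_fsredor(
                sys8, SequenceParams("fsREDOR", 10e3, times), powder_scheme(4)
            )
        with pytest.raises(InvalidSelectionError):
            simulate_fsredor(
                sys8,
                SequenceParams(
                    "fsREDOR", 10e3, times, selected_pair=("s0", "s2")
                ),  # two carbons
                powder_scheme(4),
            )
        with pytest.raises(InvalidSelectionError):
            simulate_fsredor(
                sys8,
                SequenceParams(
                    "fsREDOR", 10e3, times, selected_pair=("s0", "zz")
                ),
                powder_scheme(4),
            )
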