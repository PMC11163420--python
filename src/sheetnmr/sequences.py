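"""Dipolar-recoupling pulse-sequence simulations.

Implements rotor-synchronized REDOR (observe 13C, dephase via 15N pi
pulses at each half and full rotor period, one refocusing 13C pi pulse at
the sequence midpoint), frequency-selective REDOR (ideal pair selection),
and constant-time PITHIRDS-type 13C-13C recoupling with finite pi pulses
of one-third rotor period.

Numerical scheme: piecewise-constant Hamiltonians over sub-intervals of at
most ``max_step`` (default 1 us), matrix exponentials via eigendecomposition,
and reuse of rotor-period (REDOR) or block (PITHIRDS) propagators through
exponentiation by squaring.

For REDOR the 15N spins are exact spectators of the simulated Hamiltonian
(13C-15N and 13C-13C secular couplings only): their z projections commute
with everything, so the propagation enumerates the 2**nN classical 15N
spin-state branches and evolves only the 13C subsystem — algebraically
identical to propagating the full system, at a fraction of the cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .constants import dipolar_coupling_constant
from .curves import DephasingCurve
from .engine import (
    BinaryPower,
    collective_op,
    collective_pi_x,
    expectation,
    expm_herm,
    expm_herm_blocked,
    homonuclear_pair_op,
    iz_diagonals,
    iz_sectors,
    mas_csa_factors,
    mas_p2_factors,
    product_of_steps,
    single_spin_ops,
)
from .geometry import SpinSystem
from .powder import PowderScheme, powder_scheme

__all__ = [
    "SequenceParams",
    "InvalidSystemError",
    "InvalidSelectionError",
    "redor_times",
    "pithirds_times",
    "simulate_redor",
    "simulate_fsredor",
    "simulate_pithirds",
    "redor_universal_curve",
    "redor_product_of_cosines",
]

SEQUENCE_KINDS = ("REDOR", "fsREDOR", "PITHIRDS_CT")

#: default total block count of the constant-time PITHIRDS schedule
#: (256 blocks of 3 rotor periods = 61.44 ms at 12.5 kHz MAS)
PITHIRDS_TOTAL_BLOCKS = 256


class InvalidSystemError(ValueError):
    """The spin system cannot be simulated with the requested sequence."""


class InvalidSelectionError(ValueError):
    """A frequency-selective pair selection is invalid."""


@dataclass(frozen=True)
class SequenceParams:
    """Pulse-sequence parameters.

    ``pi_pulse_length`` of 0 means ideal delta pulses (REDOR default); the
    PITHIRDS sequence requires finite pulses of one-third rotor period and
    supplies them automatically when 0.  ``k_blocks`` optionally fixes the
    (k1, k2, k3) pulse-block budget of the constant-time PITHIRDS schedule
    through its total; ``selected_pair`` names the (13C, 15N) site pair for
    fsREDOR.  ``max_step`` bounds the piecewise-constant integration step.
    """

    sequence_kind: str
    mas_rate: float
    recoupling_times: np.ndarray
    pi_pulse_length: float = 0.0
    k_blocks: tuple[int, int, int] | None = None
    selected_pair: tuple[str, str] | None = None
    max_step: float = 1e-6

    def __post_init__(self):
        if self.sequence_kind not in SEQUENCE_KINDS:
            raise ValueError(f"unknown sequence kind {self.sequence_kind!r}")
        if self.mas_rate <= 0:
            raise ValueError("mas_rate must be positive")
        t = np.asarray(self.recoupling_times, dtype=float).ravel()
        if t.size == 0 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("recoupling_times must be non-negative, increasing")
        if self.pi_pulse_length < 0:
            raise ValueError("pi_pulse_length must be non-negative")
        if self.k_blocks is not None:
            k = tuple(int(v) for v in self.k_blocks)
            if len(k) != 3 or any(v < 0 for v in k):
                raise ValueError("k_blocks must be three non-negative integers")
            object.__setattr__(self, "k_blocks", k)
        if self.sequence_kind == "PITHIRDS_CT" and self.pi_pulse_length:
            third = 1.0 / (3.0 * self.mas_rate)
            if abs(self.pi_pulse_length - third) > 1e-12:
                raise ValueError(
                    "PITHIRDS requires pi pulses of one-third rotor period"
                )
        object.__setattr__(self, "recoupling_times", t)

    @property
    def rotor_period(self) -> float:
        return 1.0 / self.mas_rate


def redor_times(
    mas_rate: float = 10e3, t_max: float = 61.44e-3, n_points: int = 16
) -> np.ndarray:
    """Rotor-synchronized REDOR time grid: even rotor-period multiples.

    Times snap to the nearest even multiple of the rotor period (the
    sequence needs symmetric halves about the 13C refocusing pulse), so
    e.g. a requested 61.44 ms maximum at 10 kHz MAS becomes 61.4 ms.
    """
    tr = 1.0 / mas_rate
    raw = np.linspace(0.0, t_max, n_points)
    n = np.unique(2 * np.round(raw / (2 * tr)).astype(int))
    return n * tr


def pithirds_times(
    mas_rate: float = 12.5e3,
    n_points: int = 16,
    total_blocks: int = PITHIRDS_TOTAL_BLOCKS,
) -> np.ndarray:
    """Effective PITHIRDS recoupling times.

    The schedule switches between recoupling and compensation in
    supercycle units of 8 blocks (24 rotor periods, i.e. three full XY-8
    phase cycles), so times are multiples of 24 rotor periods: 1.92 ms
    steps at 12.5 kHz MAS up to the 61.44 ms constant-time budget.
    """
    super_unit = 24.0 / mas_rate
    n_super = total_blocks // 8
    k1 = np.unique(np.round(np.linspace(0, n_super, n_points)).astype(int))
    return k1 * super_unit


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------


def redor_universal_curve(d_hz, n_rotor_periods, rotor_period: float):
    """Analytic isolated-pair REDOR dephasing (powder average).

    Returns Delta S / S0 = 1 - (sqrt(2)*pi/4) * J_{1/4}(sqrt(2) lam) *
    J_{-1/4}(sqrt(2) lam) with lam = d * n * T_r; 0 at lam = 0 and -> 1 as
    lam -> infinity.
    """
    d_hz = np.asarray(d_hz, dtype=float)
    lam = d_hz * np.asarray(n_rotor_periods, dtype=float) * rotor_period
    lam, scalar = np.atleast_1d(lam), np.ndim(lam) == 0
    out = np.zeros_like(lam)
    nz = lam != 0
    x = np.sqrt(2.0) * np.abs(lam[nz])
    out[nz] = 1.0 - (np.sqrt(2.0) * np.pi / 4.0) * jv(0.25, x) * jv(-0.25, x)
    return float(out[0]) if scalar else out


def _redor_cycle_phases(
    system: SpinSystem, params: SequenceParams, powder: PowderScheme, n_quad: int = 512
) -> tuple[np.ndarray, list[int], list[int]]:
    """Per-rotor-cycle REDOR phase integrals.

    Returns (phi, c_idx, n_idx) where phi[o, i, k] is the net phase (rad)
    accumulated per rotor cycle by carbon i's coherence from 15N spin k in
    its spin-up branch, for crystallite orientation o.
    """
    isotopes = system.isotopes
    c_idx = [i for i, iso in enumerate(isotopes) if iso == "C13"]
    n_idx = [i for i, iso in enumerate(isotopes) if iso == "N15"]
    tr = params.rotor_period
    omega_r = 2.0 * np.pi * params.mas_rate
    pos = system.positions
    rot = powder.rotation_matrices()
    dt = tr / n_quad
    tmid = (np.arange(n_quad) + 0.5) * dt
    sign = np.where(tmid < tr / 2.0, 1.0, -1.0)
    phi = np.zeros((len(powder), len(c_idx), len(n_idx)))
    for a, i in enumerate(c_idx):
        for b, k in enumerate(n_idx):
            rvec = pos[k] - pos[i]
            r = np.linalg.norm(rvec)
            bcoup = 2.0 * np.pi * dipolar_coupling_constant("C13", "N15", r)
            u = rot @ (rvec / r)
            f = mas_p2_factors(u, omega_r, tmid)  # (O, T)
            phi[:, a, b] = bcoup * np.sum(f * sign, axis=-1) * dt
    return phi, c_idx, n_idx


def redor_product_of_cosines(
    system: SpinSystem,
    params: SequenceParams,
    powder: PowderScheme | None = None,
    n_quad: int = 512,
) -> DephasingCurve:
    """Commuting-limit REDOR closed form: 1 - <prod_k cos(n*phi_k)>.

    Valid when homonuclear couplings are absent (or removed); serves as the
    independent oracle for the numerical engine in that limit.
    """
    powder = powder if powder is not None else powder_scheme(377)
    phi, c_idx, n_idx = _redor_cycle_phases(system, params, powder, n_quad)
    tr = params.rotor_period
    ns = _rotor_cycle_counts(params.recoupling_times, tr)
    vals = []
    for n in ns:
        per_c = np.prod(np.cos(n * phi), axis=-1)  # (O, nC)
        s = np.sum(powder.weights[:, None] * per_c, axis=0).mean()
        vals.append(1.0 - s)
    return DephasingCurve(ns * tr, np.array(vals), "delta_S_over_S0")


# ---------------------------------------------------------------------------
# REDOR engine
# ---------------------------------------------------------------------------


def _rotor_cycle_counts(times: np.ndarray, tr: float) -> np.ndarray:
    n = np.round(times / tr).astype(int)
    if not np.allclose(n * tr, times, rtol=0.0, atol=1e-12):
        raise ValueError("recoupling times must be integer multiples of the rotor period")
    if np.any(n % 2):
        raise ValueError("REDOR recoupling times must be even rotor-period multiples")
    return n


def _spin_branches(n_spins: int) -> np.ndarray:
    """(2**n, n) array of +-1/2 z projections."""
    idx = np.arange(2**n_spins)
    bits = (idx[:, None] >> (n_spins - 1 - np.arange(n_spins)[None, :])) & 1
    return 0.5 - bits.astype(float)


def simulate_redor(
    system: SpinSystem,
    params: SequenceParams,
    powder: PowderScheme | None = None,
) -> DephasingCurve:
    """Simulate a powder-averaged 13C-observe REDOR dephasing curve.

    The returned curve is Delta S/S0 = 1 - S/S0 where S includes the 15N
    dephasing pulses and S0 is the same propagation without them; both
    include all 13C-13C homonuclear couplings.  A system with 13C but no
    15N yields the flat zero curve (no heteronuclear coupling to recouple).
    """
    powder = powder if powder is not None else powder_scheme(377)
    isotopes = system.isotopes
    c_idx = [i for i, iso in enumerate(isotopes) if iso == "C13"]
    n_idx = [i for i, iso in enumerate(isotopes) if iso == "N15"]
    if not c_idx:
        raise InvalidSystemError("REDOR needs at least one 13C site to observe")
    if len(n_idx) > 10:
        raise InvalidSystemError("more than 10 15N spectator spins is not supported")
    tr = params.rotor_period
    ns = _rotor_cycle_counts(params.recoupling_times, tr)
    if not n_idx:
        return DephasingCurve(ns * tr, np.zeros(len(ns)), "delta_S_over_S0")

    nC, nN = len(c_idx), len(n_idx)
    dim = 2**nC
    omega_r = 2.0 * np.pi * params.mas_rate
    pos = system.positions

    # steps per rotor period, even so the half-period boundary is a step edge
    m = 2 * max(1, int(np.ceil(tr / (2.0 * params.max_step))))
    dt = tr / m
    tmid = (np.arange(m) + 0.5) * dt

    # pair data
    cc_pairs = [(a, b) for a in range(nC) for b in range(a + 1, nC)]
    cn_pairs = [(a, b) for a in range(nC) for b in range(nN)]

    def pair_vec_coup(i, j, iso_i, iso_j):
        rvec = pos[j] - pos[i]
        r = np.linalg.norm(rvec)
        return rvec / r, 2.0 * np.pi * dipolar_coupling_constant(iso_i, iso_j, r)

    rot = powder.rotation_matrices()  # (O, 3, 3)
    n_orient = len(powder)

    ops_cc = np.array(
        [homonuclear_pair_op(nC, a, b) for a, b in cc_pairs]
    ).real if cc_pairs else np.zeros((0, dim, dim))
    zdiag = iz_diagonals(nC)  # (nC, dim)
    sig = _spin_branches(nN)  # (B, nN)
    n_branch = sig.shape[0]
    # branch index map sigma -> -sigma (bitwise complement)
    neg = (2**nN - 1) - np.arange(n_branch)

    xc = collective_pi_x(nC)
    obs = collective_op(nC, "x").real
    obs_norm = np.trace(obs @ obs).real

    # orientation chunking to bound memory
    bytes_target = 2e8
    chunk = max(1, int(bytes_target / (n_branch * m * dim * dim * 16)))
    s_sum = np.zeros(len(ns))
    s0_sum = np.zeros(len(ns))
    max_half = int(ns.max()) // 2 if len(ns) else 0

    for start in range(0, n_orient, chunk):
        sel = slice(start, min(start + chunk, n_orient))
        r_chunk = rot[sel]
        w_chunk = powder.weights[sel]
        oc = r_chunk.shape[0]

        # homonuclear part (oc, m, dim, dim)
        h_cc = np.zeros((oc, m, dim, dim))
        if cc_pairs:
            amps = []
            for (a, b) in cc_pairs:
                u, bc = pair_vec_coup(c_idx[a], c_idx[b], "C13", "C13")
                amps.append(bc * mas_p2_factors(r_chunk @ u, omega_r, tmid))
            h_cc = np.einsum("pot,pij->otij", np.array(amps), ops_cc)

        # heteronuclear diagonal per branch (B, oc, m, dim)
        hdiag = np.zeros((n_branch, oc, m, dim))
        for (a, b) in cn_pairs:
            u, bc = pair_vec_coup(c_idx[a], n_idx[b], "C13", "N15")
            amp = bc * mas_p2_factors(r_chunk @ u, omega_r, tmid)  # (oc, m)
            hdiag += (
                2.0 * sig[:, b][:, None, None, None]
                * amp[None, :, :, None]
                * zdiag[a][None, None, None, :]
            )

        h = h_cc[None] + hdiag[..., None] * np.eye(dim)
        steps = expm_herm(h, dt)  # (B, oc, m, dim, dim)
        del h, hdiag

        # period propagators: pattern with 15N pulses flips the sign of the
        # heteronuclear term each half period; a sign flip equals swapping
        # the branch sigma -> -sigma, so everything derives from the
        # all-plus step set.
        first = product_of_steps(np.moveaxis(steps[:, :, : m // 2], 2, 0))
        second = product_of_steps(np.moveaxis(steps[:, :, m // 2 :], 2, 0))
        u_a = second[neg] @ first  # dephasing pattern, first sequence half
        u_c = second @ first  # no 15N pulses (S0)
        u_b = u_a[neg]  # dephasing pattern after the 13C midpoint pulse
        del steps, first, second

        pow_a = BinaryPower(u_a, max_half)
        pow_b = BinaryPower(u_b, max_half)
        pow_c = BinaryPower(u_c, max_half)
        for it, n in enumerate(ns):
            half = int(n) // 2
            u_s = pow_b.power(half) @ xc @ pow_a.power(half)
            u_s0 = pow_c.power(half) @ xc @ pow_c.power(half)
            sig_s = expectation(u_s, obs, obs) / obs_norm  # (B, oc)
            sig_s0 = expectation(u_s0, obs, obs) / obs_norm
            s_sum[it] += (w_chunk[None, :] * sig_s).sum() / n_branch
            s0_sum[it] += (w_chunk[None, :] * sig_s0).sum() / n_branch

    values = 1.0 - s_sum / s0_sum
    if np.any(values < -0.05) or np.any(values > 1.05):
        warnings.warn(
            "REDOR dephasing outside [-0.05, 1.05]: multi-spin transients "
            "can overshoot complete dephasing slightly; large excursions "
            "indicate a powder or time-step problem"
        )
    values[np.abs(values) < 1e-12] = 0.0
    return DephasingCurve(ns * tr, values, "delta_S_over_S0")


def simulate_fsredor(
    system: SpinSystem,
    params: SequenceParams,
    powder: PowderScheme | None = None,
) -> DephasingCurve:
    """Frequency-selective REDOR under the ideal-selectivity model.

    The frequency-selective pulses isolate one 13C-15N pair and remove
    homonuclear couplings; the simulation therefore equals plain REDOR on
    the reduced two-spin system of the selected pair.
    """
    if params.selected_pair is None:
        raise InvalidSelectionError("fsREDOR requires params.selected_pair")
    id_c, id_n = params.selected_pair
    lookup = {s.site_id: s for s in system.sites}
    missing = [i for i in (id_c, id_n) if i not in lookup]
    if missing:
        raise InvalidSelectionError(f"selected_pair sites not found: {missing}")
    pair = {lookup[id_c].isotope, lookup[id_n].isotope}
    if pair != {"C13", "N15"}:
        raise InvalidSelectionError(
            "selected_pair must contain one 13C and one 15N site"
        )
    sub = system.select([id_c, id_n], name=f"{system.name}:{id_c}-{id_n}")
    return simulate_redor(sub, params, powder)


# ---------------------------------------------------------------------------
# PITHIRDS-CT engine
# ---------------------------------------------------------------------------


def _csa_tensors_rad(system: SpinSystem, c_idx: list[int]) -> np.ndarray | None:
    """Traceless CSA tensors (rad/s) in the molecular frame, or None."""
    from .constants import B0_TESLA, larmor_frequency

    if all(system.sites[i].csa is None for i in c_idx):
        return None
    omega0 = 2.0 * np.pi * larmor_frequency("C13", B0_TESLA)
    tensors = np.zeros((len(c_idx), 3, 3))
    for a, i in enumerate(c_idx):
        csa = system.sites[i].csa
        if csa is None:
            continue
        pas = np.diag(csa.principal_values()) * 1e-6 * omega0
        ang = np.deg2rad([csa.alpha_deg, csa.beta_deg, csa.gamma_deg])
        rz1 = _rot_z(ang[0])
        ry = _rot_y(ang[1])
        rz2 = _rot_z(ang[2])
        r = rz1 @ ry @ rz2
        tensors[a] = r @ pas @ r.T
    return tensors


def _rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _pithirds_k_schedule(
    times: np.ndarray, super_unit: float, n_super: int
) -> list[tuple[int, int, int]]:
    """Superblock counts (recoupling, leading comp, trailing comp)."""
    k1 = np.round(times / super_unit).astype(int)
    if not np.allclose(k1 * super_unit, times, rtol=0.0, atol=1e-12):
        raise ValueError(
            "PITHIRDS recoupling times must be multiples of 24 rotor periods "
            "(8 pulse blocks, one XY-8 supercycle unit)"
        )
    if k1.max(initial=0) > n_super:
        raise ValueError("recoupling time exceeds the constant-time budget")
    out = []
    for k in k1:
        rest = n_super - int(k)
        out.append((int(k), (rest + 1) // 2, rest // 2))
    return out


def simulate_pithirds(
    system: SpinSystem,
    params: SequenceParams,
    powder: PowderScheme | None = None,
) -> DephasingCurve:
    """Constant-time 13C-13C recoupling decay, S/S0 vs recoupling time.

    The sequence alternates two kinds of constant-duration units of 24
    rotor periods (8 blocks of 3): recoupling units carry one finite pi
    pulse of one-third rotor period per rotor period, phased on the XY-8
    supercycle (x y x y y x y x, net rotation identity) so the pulse
    train stays robust against the large carbonyl CSA; compensation units
    are rotor-synchronized free-evolution delays, over which MAS averages
    the secular dipolar and CSA interactions to first order.  The block
    budget ``k1 + k2 + k3`` fixes the total duration (256 blocks of three
    rotor periods by default = 61.44 ms at 12.5 kHz); the effective
    recoupling time is the recoupled fraction of that fixed total, in
    steps of 24 rotor periods (1.92 ms at 12.5 kHz).  CSA is included for
    sites that carry tensors; non-13C sites are ignored.
    """
    powder = powder if powder is not None else powder_scheme(89)
    c_idx = [i for i, iso in enumerate(system.isotopes) if iso == "C13"]
    if not c_idx:
        raise InvalidSystemError("PITHIRDS needs at least one 13C site")
    nC = len(c_idx)
    dim = 2**nC
    tr = params.rotor_period
    omega_r = 2.0 * np.pi * params.mas_rate
    tau_p = params.pi_pulse_length or tr / 3.0
    omega1 = np.pi / tau_p
    total_blocks = sum(params.k_blocks) if params.k_blocks else PITHIRDS_TOTAL_BLOCKS
    if total_blocks % 8:
        raise ValueError("total block count must be a multiple of 8 (XY-8 unit)")
    n_super = total_blocks // 8
    super_unit = 24.0 * tr
    schedule = _pithirds_k_schedule(params.recoupling_times, super_unit, n_super)
    # the S0 reference is the zero-recoupling point of the same constant-time
    # sequence; prepend it if the requested grid does not include t = 0
    has_zero = bool(schedule) and schedule[0][0] == 0
    if not has_zero:
        schedule = [(0, (n_super + 1) // 2, n_super // 2)] + schedule

    pos = system.positions
    rot = powder.rotation_matrices()
    n_orient = len(powder)
    sectors = iz_sectors(nC)

    cc_pairs = [(a, b) for a in range(nC) for b in range(a + 1, nC)]
    ops_cc = (
        np.array([homonuclear_pair_op(nC, a, b) for a, b in cc_pairs])
        if cc_pairs
        else np.zeros((0, dim, dim), dtype=complex)
    )
    pair_u, pair_b = [], []
    for a, b in cc_pairs:
        rvec = pos[c_idx[b]] - pos[c_idx[a]]
        r = np.linalg.norm(rvec)
        pair_u.append(rvec / r)
        pair_b.append(2.0 * np.pi * dipolar_coupling_constant("C13", "C13", r))
    pair_u = np.array(pair_u).reshape(-1, 3)
    pair_b = np.array(pair_b)

    zops = single_spin_ops(nC)[2]  # (nC, dim, dim)
    csa_mol = _csa_tensors_rad(system, c_idx)
    jx = collective_op(nC, "x")
    obs = jx.real
    obs_norm = np.trace(obs @ obs).real
    # diagonal of exp(-i*phi*Jz): global z rotations commute with the
    # secular dipolar + CSA Hamiltonian, so a pulse of phase phi is the
    # z-rotated x-phase pulse period: U(phi) = Rz(phi) U(x) Rz(-phi)
    mz = iz_diagonals(nC).sum(axis=0)
    xy8 = (0.0, 0.5 * np.pi, 0.0, 0.5 * np.pi, 0.5 * np.pi, 0.0, 0.5 * np.pi, 0.0)

    def free_hamiltonians(r_chunk, t0, dt, n_steps, n_sub=8):
        """(O, n_steps, dim, dim) step-averaged dipolar + CSA Hamiltonians.

        Coefficients are averaged over ``n_sub`` samples per step, so the
        piecewise-constant propagator integrates the rapid MAS modulation
        accurately even with coarse steps.
        """
        oc = r_chunk.shape[0]
        tt = t0 + dt * (
            np.arange(n_steps)[:, None] + (np.arange(n_sub)[None, :] + 0.5) / n_sub
        ).ravel()
        h = np.zeros((oc, n_steps, dim, dim))
        if cc_pairs:
            u_rot = np.einsum("oab,pb->opa", r_chunk, pair_u)
            f = mas_p2_factors(u_rot, omega_r, tt)
            f = f.reshape(oc, len(cc_pairs), n_steps, n_sub).mean(axis=-1)
            h += np.einsum("p,opt,pij->otij", pair_b, f, ops_cc.real)
        if csa_mol is not None:
            a_rot = np.einsum("oab,sbc,odc->osad", r_chunk, csa_mol, r_chunk)
            g = mas_csa_factors(a_rot, omega_r, tt)
            g = g.reshape(oc, len(c_idx), n_steps, n_sub).mean(axis=-1)
            h += np.einsum("ost,sij->otij", g, zops.real)
        return h

    s_vals = np.zeros(len(schedule))
    steps_per_pulse = max(1, int(np.ceil(tau_p / params.max_step)))
    chunk = max(1, int(3e8 / (dim * dim * 32 * steps_per_pulse)))
    max_k = max(max(k) for k in schedule) if schedule else 0

    for start in range(0, n_orient, chunk):
        sel = slice(start, min(start + chunk, n_orient))
        r_chunk = rot[sel]
        w_chunk = powder.weights[sel]
        oc = r_chunk.shape[0]
        eye = np.broadcast_to(np.eye(dim, dtype=complex), (oc, dim, dim)).copy()

        def free_propagator(t0, duration):
            """Stepped free MAS evolution (keeps second-order dipolar terms).

            Processed in bounded slices of steps so long delays (the
            compensation units span 24 rotor periods) stay within memory.
            """
            n_steps = max(1, int(np.ceil(12.0 * duration / tr)))
            dt = duration / n_steps
            u = eye.copy()
            max_slice = 24
            for s0 in range(0, n_steps, max_slice):
                n_sl = min(max_slice, n_steps - s0)
                h = free_hamiltonians(r_chunk, t0 + s0 * dt, dt, n_sl)
                u_steps = expm_herm_blocked(h.astype(complex), dt, sectors)
                u = product_of_steps(np.moveaxis(u_steps, 1, 0)) @ u
            return u

        def pulse_period_propagator():
            """One rotor period: x-phase pulse of tau_p, then free evolution."""
            dt = tau_p / steps_per_pulse
            h = free_hamiltonians(r_chunk, 0.0, dt, steps_per_pulse)
            u_steps = expm_herm(h + (omega1 * jx)[None, None], dt)
            u = product_of_steps(np.moveaxis(u_steps, 1, 0))
            return free_propagator(tau_p, tr - tau_p) @ u

        base = pulse_period_propagator()

        # recoupling unit: 24 pulse periods on the XY-8 phase supercycle;
        # a phase-phi pulse period is the z-rotated x-phase period
        u_rec = eye.copy()
        for j in range(24):
            phi = xy8[j % 8]
            if phi:
                d = np.exp(-1j * phi * mz)
                u_rec = ((d[:, None] * base) * d.conj()[None, :]) @ u_rec
            else:
                u_rec = base @ u_rec
        # compensation unit: rotor-synchronized free evolution, 24 periods
        u_comp = free_propagator(0.0, 24.0 * tr)

        pow_rec = BinaryPower(u_rec, max_k)
        pow_comp = BinaryPower(u_comp, max_k)
        for it, (k1, k2, k3) in enumerate(schedule):
            u_total = (
                pow_comp.power(k3) @ pow_rec.power(k1) @ pow_comp.power(k2)
            )
            sig = expectation(u_total, obs, obs) / obs_norm  # (oc,)
            s_vals[it] += float(np.dot(w_chunk, sig))

    values = s_vals / s_vals[0]
    if not has_zero:
        values = values[1:]
    return DephasingCurve(
        params.recoupling_times, values, "S_over_S0", strict=False
    )
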