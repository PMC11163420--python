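"""Low-level spin-dynamics machinery.

Dense spin-1/2 operator algebra, MAS time modulation of secular couplings,
and batched piecewise-constant propagation.  Conventions:

* Hilbert-space basis: tensor product over sites in system order, spin-up
  first (index bit 0 = up), site 0 on the most significant bit.
* The rotor axis is the rotor-frame z axis, tilted by the magic angle from
  the static field.  Crystallite rotations map molecule-frame vectors and
  tensors into the rotor frame; the MAS rotation is applied analytically
  through the time dependence of the field direction in the rotor frame.
* Secular dipolar coupling amplitude: omega(t) = b * P2(cos theta(t)) in
  rad/s, with b = 2*pi*d and theta(t) the internuclear-vector angle to the
  static field.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .constants import MAGIC_ANGLE

_SIN_M = np.sin(MAGIC_ANGLE)
_COS_M = np.cos(MAGIC_ANGLE)


# ---------------------------------------------------------------------------
# spin operators
# ---------------------------------------------------------------------------

_SX = np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex)
_SY = np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex)
_SZ = np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex)
_ID = np.eye(2, dtype=complex)


@lru_cache(maxsize=32)
def single_spin_ops(n_spins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Ix, Iy, Iz) stacks of shape (n_spins, 2**n, 2**n)."""
    ops = {"x": [], "y": [], "z": []}
    for i in range(n_spins):
        for key, s in (("x", _SX), ("y", _SY), ("z", _SZ)):
            m = np.array([[1.0 + 0j]])
            for j in range(n_spins):
                m = np.kron(m, s if j == i else _ID)
            ops[key].append(m)
    return (np.array(ops["x"]), np.array(ops["y"]), np.array(ops["z"]))


def iz_diagonals(n_spins: int) -> np.ndarray:
    """Diagonal of Iz for each spin, shape (n_spins, 2**n); entries +-1/2."""
    dim = 2**n_spins
    idx = np.arange(dim)
    bits = (idx[None, :] >> (n_spins - 1 - np.arange(n_spins)[:, None])) & 1
    return 0.5 - bits.astype(float)


def homonuclear_pair_op(n_spins: int, i: int, j: int) -> np.ndarray:
    """Secular homonuclear dipolar operator 2*Izi*Izj - (Ixi*Ixj + Iyi*Iyj)."""
    ix, iy, iz = single_spin_ops(n_spins)
    return 2.0 * iz[i] @ iz[j] - ix[i] @ ix[j] - iy[i] @ iy[j]


def collective_op(n_spins: int, axis: str) -> np.ndarray:
    ix, iy, iz = single_spin_ops(n_spins)
    return {"x": ix, "y": iy, "z": iz}[axis].sum(axis=0)


def collective_pi_x(n_spins: int) -> np.ndarray:
    """Ideal collective pi pulse about x (global phase irrelevant)."""
    jx = collective_op(n_spins, "x")
    return expm_herm(jx[None], np.pi)[0]


def iz_sectors(n_spins: int) -> list[np.ndarray]:
    """Basis-index groups of constant total Iz (conserved by secular
    homonuclear couplings and Iz terms)."""
    idx = np.arange(2**n_spins)
    pop = np.array([bin(i).count("1") for i in idx])
    return [idx[pop == k] for k in range(n_spins + 1)]


# ---------------------------------------------------------------------------
# MAS time dependence
# ---------------------------------------------------------------------------


def field_direction_in_rotor_frame(omega_r: float, times: np.ndarray) -> np.ndarray:
    """Unit vector of the static field in the rotor frame, shape (T, 3)."""
    wt = omega_r * np.asarray(times, dtype=float)
    return np.stack(
        [-_SIN_M * np.cos(wt), _SIN_M * np.sin(wt), np.full_like(wt, _COS_M)],
        axis=-1,
    )


def mas_p2_factors(
    u_rotor: np.ndarray, omega_r: float, times: np.ndarray
) -> np.ndarray:
    """P2(cos theta(t)) for unit vectors already rotated into the rotor frame.

    Parameters
    ----------
    u_rotor:
        (..., 3) unit internuclear vectors in the rotor frame.
    omega_r:
        Rotor angular frequency, rad/s.
    times:
        (T,) evaluation times, s.

    Returns
    -------
    (..., T) array of (3 cos^2 theta - 1)/2.
    """
    v = field_direction_in_rotor_frame(omega_r, times)  # (T, 3)
    cos_t = np.tensordot(u_rotor, v, axes=([-1], [-1]))  # (..., T)
    return 0.5 * (3.0 * cos_t**2 - 1.0)


def mas_csa_factors(
    tensor_rotor: np.ndarray, omega_r: float, times: np.ndarray
) -> np.ndarray:
    """Instantaneous zz-lab component of traceless tensors under MAS.

    ``tensor_rotor``: (..., 3, 3) tensors in the rotor frame; returns
    (..., T) values of v(t)^T A v(t) with v the field direction.
    """
    v = field_direction_in_rotor_frame(omega_r, times)  # (T, 3)
    av = np.einsum("...ab,tb->...ta", tensor_rotor, v)
    return np.einsum("...ta,ta->...t", av, v)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def expm_herm(h: np.ndarray, dt: float) -> np.ndarray:
    """exp(-i * h * dt) for batched Hermitian matrices (..., d, d)."""
    w, vec = np.linalg.eigh(h)
    phase = np.exp(-1j * w * dt)
    return (vec * phase[..., None, :]) @ vec.conj().swapaxes(-1, -2)


def expm_herm_blocked(
    h: np.ndarray, dt: float, sectors: list[np.ndarray]
) -> np.ndarray:
    """exp(-i*h*dt) exploiting block structure over conserved sectors.

    ``h`` must be block diagonal with respect to ``sectors`` (not checked).
    """
    out = np.zeros_like(h, dtype=complex)
    for idx in sectors:
        block = h[..., idx[:, None], idx[None, :]]
        out[..., idx[:, None], idx[None, :]] = expm_herm(block, dt)
    return out


def product_of_steps(steps: np.ndarray) -> np.ndarray:
    """Time-ordered product of step propagators.

    ``steps``: (S, ..., d, d); returns steps[S-1] @ ... @ steps[0].
    """
    out = steps[0]
    for s in range(1, steps.shape[0]):
        out = steps[s] @ out
    return out


class BinaryPower:
    """Cached binary powers for batched matrix exponentiation by squaring."""

    def __init__(self, u: np.ndarray, max_exponent: int):
        self._pows = [u]
        k = 1
        while k * 2 <= max(1, max_exponent):
            self._pows.append(self._pows[-1] @ self._pows[-1])
            k *= 2

    def power(self, n: int) -> np.ndarray:
        u = self._pows[0]
        if n == 0:
            eye = np.zeros_like(u)
            eye[...] = np.eye(u.shape[-1])
            return eye
        out = None
        bit = 0
        while n:
            if n & 1:
                p = self._pows[bit]
                out = p if out is None else p @ out
            n >>= 1
            bit += 1
        return out


def expectation(u: np.ndarray, rho: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Re Tr(U rho U^H obs) for batched propagators."""
    evolved = u @ rho @ u.conj().swapaxes(-1, -2)
    return np.einsum("...ij,ji->...", evolved, obs).real
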