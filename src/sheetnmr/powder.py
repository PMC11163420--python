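"""Powder orientation schemes for magic-angle-spinning simulations.

A crystallite orientation is a rotation taking molecule-frame vectors into
the rotor frame (rotor axis = z), parameterized by z-y-z Euler angles
(alpha, beta, gamma): ``R = Rz(alpha) @ Ry(beta) @ Rz(gamma)``.  The outer
pair (alpha, beta) fixes the direction of the molecular z axis on the
sphere; the inner gamma matters only for tensors that are not axially
symmetric about the molecular z axis (e.g. CSA with eta != 0 on a linear
spin array).

All schemes are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PowderScheme", "powder_scheme"]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class PowderScheme:
    """A set of crystallite orientations with normalized weights."""

    orientations: np.ndarray  #: (n, 3) Euler angles (alpha, beta, gamma), rad
    weights: np.ndarray  #: (n,) positive, summing to 1

    def __post_init__(self):
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        w = np.asarray(self.weights, dtype=float).ravel()
        if ori.shape[0] < 1 or ori.shape[1] != 3:
            raise ValueError("orientations must be a non-empty (n, 3) array")
        if w.shape[0] != ori.shape[0]:
            raise ValueError("weights length must match orientations")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.orientations.shape[0]

    def rotation_matrices(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices, molecule frame -> rotor frame."""
        a, b, g = self.orientations.T
        return _rz(a) @ _ry(b) @ _rz(g)

    def with_inner_angles(self, n_gamma: int) -> "PowderScheme":
        """Tensor-product extension with ``n_gamma`` inner (gamma) angles.

        Needed for crystallites carrying tensors that are not axially
        symmetric about the molecular z axis.
        """
        if n_gamma < 1:
            raise ValueError("n_gamma must be >= 1")
        gammas = 2.0 * np.pi * np.arange(n_gamma) / n_gamma
        ori = np.repeat(self.orientations, n_gamma, axis=0)
        ori[:, 2] = np.tile(gammas, len(self))
        w = np.repeat(self.weights, n_gamma) / n_gamma
        return PowderScheme(ori, w)


def _rz(t: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(t)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros(t.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _ry(t: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(t)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros(t.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    out[..., 1, 1] = 1.0
    return out


def powder_scheme(n_orientations: int, method: str = "repulsion-like") -> PowderScheme:
    """Deterministic powder scheme with ``n_orientations`` points.

    Parameters
    ----------
    n_orientations:
        Number of crystallite orientations (>= 1).
    method:
        ``"repulsion-like"`` — golden-ratio (Fibonacci) spiral on the
        sphere, quasi-uniform with equal weights; the default 377-point
        scheme used throughout the package is of this kind.
        ``"grid"`` — Gauss-Legendre nodes in cos(beta) crossed with a
        uniform alpha grid, with quadrature weights.
    """
    n = int(n_orientations)
    if n < 1:
        raise ValueError("n_orientations must be >= 1")
    if method == "repulsion-like":
        # quasi-uniform over SO(3): golden-ratio spiral for (alpha, beta)
        # plus an independent low-discrepancy (sqrt(2)) sequence for the
        # inner gamma, so the image of ANY fixed molecular direction is
        # asymptotically isotropic, not just the molecular z axis
        i = np.arange(n)
        cosb = 1.0 - (2.0 * i + 1.0) / n
        beta = np.arccos(np.clip(cosb, -1.0, 1.0))
        alpha = np.mod(2.0 * np.pi * i / _GOLDEN, 2.0 * np.pi)
        gamma = np.mod(2.0 * np.pi * i * np.sqrt(2.0), 2.0 * np.pi)
        ori = np.column_stack([alpha, beta, gamma])
        return PowderScheme(ori, np.full(n, 1.0 / n))
    if method == "grid":
        ng = 3 if n >= 18 else 1
        nb = max(1, int(round(np.sqrt(n / (2.0 * ng)))))
        na = max(1, n // (nb * ng))
        nodes, wts = np.polynomial.legendre.leggauss(nb)
        beta = np.arccos(nodes)
        alpha = 2.0 * np.pi * (np.arange(na) + 0.5) / na
        gamma = 2.0 * np.pi * (np.arange(ng) + 0.5) / ng
        aa, bb, gg = np.meshgrid(alpha, beta, gamma, indexing="ij")
        ww = np.broadcast_to(wts[None, :, None] / (na * ng), (na, nb, ng))
        ori = np.column_stack([aa.ravel(), bb.ravel(), gg.ravel()])
        return PowderScheme(ori, ww.ravel() / ww.sum())
    raise ValueError(f"unknown powder method: {method!r}")


def default_scheme() -> PowderScheme:
    """The package default: 377-point golden-ratio scheme."""
    return powder_scheme(377, "repulsion-like")
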