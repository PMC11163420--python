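"""Dephasing-curve container and interpolation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["DephasingCurve", "interpolate_curve", "GridError"]

#: allowed conventions: delta_S_over_S0 starts at 0, S_over_S0 starts at 1
CONVENTIONS = ("delta_S_over_S0", "S_over_S0")


class GridError(ValueError):
    """Time grids are incompatible."""


@dataclass(frozen=True)
class DephasingCurve:
    """A recoupling-time series of dimensionless dephasing intensities.

    ``strict=False`` relaxes the t=0 convention check (used for noisy
    synthetic data, where the t=0 sample carries noise like any other).
    """

    times: np.ndarray  #: seconds, non-negative, strictly increasing
    values: np.ndarray  #: dimensionless
    convention: str = "delta_S_over_S0"
    strict: bool = True

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        v = np.asarray(self.values, dtype=float).ravel()
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size == 0:
            raise ValueError("curve must be non-empty")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.strict and t[0] == 0.0:
            expected = 0.0 if self.convention == "delta_S_over_S0" else 1.0
            if abs(v[0] - expected) > 1e-6:
                raise ValueError(
                    f"value at t=0 must be {expected} for {self.convention}, got {v[0]}"
                )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def as_delta(self) -> "DephasingCurve":
        """Return the curve in the delta_S_over_S0 convention."""
        if self.convention == "delta_S_over_S0":
            return self
        return DephasingCurve(
            self.times, 1.0 - self.values, "delta_S_over_S0", strict=self.strict
        )

    def as_s_over_s0(self) -> "DephasingCurve":
        if self.convention == "S_over_S0":
            return self
        return DephasingCurve(
            self.times, 1.0 - self.values, "S_over_S0", strict=self.strict
        )

    def same_grid(self, other: "DephasingCurve", tol: float = 1e-12) -> bool:
        return len(self) == len(other) and np.allclose(
            self.times, other.times, rtol=0.0, atol=tol
        )


def interpolate_curve(curve: DephasingCurve, target_times) -> DephasingCurve:
    """Monotone-preserving (PCHIP) interpolation onto ``target_times``.

    Exact at the source knots; linear segments interpolate linearly.
    Extrapolation outside the source range raises :class:`GridError`.
    """
    tt = np.asarray(target_times, dtype=float).ravel()
    if tt.min() < curve.times.min() - 1e-15 or tt.max() > curve.times.max() + 1e-15:
        raise GridError(
            "target times extend outside the source range "
            f"[{curve.times.min()}, {curve.times.max()}]"
        )
    if len(curve) == 1:
        vals = np.full_like(tt, curve.values[0])
    else:
        vals = PchipInterpolator(curve.times, curve.values)(tt)
    # snap knot coincidences to exact source values
    idx = np.searchsorted(curve.times, tt)
    idx = np.clip(idx, 0, len(curve) - 1)
    exact = np.isclose(tt, curve.times[idx], rtol=0.0, atol=1e-15)
    vals[exact] = curve.values[idx[exact]]
    return DephasingCurve(tt, vals, curve.convention, strict=curve.strict)
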