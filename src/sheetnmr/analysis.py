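"""Peak-intensity extraction and population-mixture fitting.

The mixture fit decomposes an observed dephasing curve into a convex
combination of simulated basis curves plus an implicit non-dephasing
("uncoupled") remainder — the flat zero line in the Delta S/S0 convention.
This is the estimator behind population statements like "9% of pairs are
close enough to couple" or "22% antiparallel / 78% parallel": the fitted
fraction of the corresponding simulated geometry's curve.

The constrained least-squares problem (each fraction in [0, 1], sum <= 1)
is solved exactly by enumerating the active sets of the small convex QP,
so a single-basis fit reproduces the closed-form clipped projection to
machine precision.  95% intervals come from a residual bootstrap with a
fixed default seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .constants import NATURAL_ABUNDANCE_C13
from .curves import DephasingCurve, GridError, interpolate_curve

__all__ = [
    "PeakFit",
    "MixtureFitResult",
    "FitFailureError",
    "ConditioningError",
    "fit_gaussian_peak",
    "natural_abundance_correction",
    "natural_abundance_fraction",
    "fit_mixture",
    "interpolate_curve",
]

BOOTSTRAP_SEED = 20240524


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConditioningError(ValueError):
    """Basis curves are too collinear to separate."""


@dataclass(frozen=True)
class PeakFit:
    """One fitted Gaussian component: amp * exp(-(x-center)^2 / (2 width^2))."""

    center: float
    width: float  # Gaussian sigma, axis units
    amplitude: float
    amplitude_ci95: tuple[float, float]

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        lo, hi = self.amplitude_ci95
        if not lo <= self.amplitude <= hi:
            raise ValueError("ci95 must contain the amplitude")

    @property
    def area(self) -> float:
        return self.amplitude * self.width * np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureFitResult:
    """Population fractions of basis curves (remainder = uncoupled)."""

    fractions: np.ndarray
    fraction_ci95: np.ndarray  # (K, 2)
    residual_rms: float
    basis_names: tuple[str, ...]
    uncoupled_fraction: float

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        ci = np.asarray(self.fraction_ci95, dtype=float).reshape(-1, 2)
        if np.any(f < -1e-9) or np.any(f > 1.0 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")
        if f.sum() > 1.0 + 1e-9:
            raise ValueError("fractions must sum to at most 1")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "fraction_ci95", ci)


def _gaussian_sum(x, *theta):
    n = len(theta) // 3
    out = np.zeros_like(x, dtype=float)
    for i in range(n):
        a, c, s = theta[3 * i : 3 * i + 3]
        out += a * np.exp(-0.5 * ((x - c) / s) ** 2)
    return out


def fit_gaussian_peak(
    axis,
    intensity,
    window: tuple[float, float],
    n_components: int = 1,
) -> list[PeakFit]:
    """Fit ``n_components`` Gaussians to a spectral window by least squares.

    Under i.i.d. Gaussian noise this is the maximum-likelihood estimate;
    95% amplitude intervals use the fit covariance and a t distribution.
    Initialization is deterministic: component centers at the tallest
    local maxima in the window (ties broken toward the lower axis value),
    widths at one quarter of the window width.

    Returns components sorted by center.
    """
    x = np.asarray(axis, dtype=float).ravel()
    y = np.asarray(intensity, dtype=float).ravel()
    lo, hi = min(window), max(window)
    if lo < x.min() - 1e-9 or hi > x.max() + 1e-9:
        raise ValueError("window must lie within the axis range")
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 5:
        raise ValueError("need at least 5 samples inside the window")
    if mask.sum() < 3 * n_components + 1:
        raise ValueError("too few samples for the requested component count")
    xw, yw = x[mask], y[mask]
    order = np.argsort(xw)
    xw, yw = xw[order], yw[order]

    # deterministic initialization
    peaks, props = signal.find_peaks(yw, height=-np.inf)
    if len(peaks):
        rank = sorted(peaks, key=lambda i: (-yw[i], xw[i]))
    else:
        rank = []
    centers0 = [xw[i] for i in rank[:n_components]]
    while len(centers0) < n_components:
        centers0.append(lo + (hi - lo) * (len(centers0) + 1) / (n_components + 1))
    centers0 = sorted(centers0)
    sigma0 = (hi - lo) / 4.0
    amp0 = max(yw.max(), 1e-12)
    p0, lower, upper = [], [], []
    for c0 in centers0:
        p0 += [amp0, c0, sigma0]
        lower += [0.0, lo, (hi - lo) * 1e-3]
        upper += [np.inf, hi, (hi - lo) * 2.0]
    try:
        popt, pcov = optimize.curve_fit(
            _gaussian_sum, xw, yw, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(
            "Gaussian peak fit did not converge",
            {"window": (lo, hi), "n_components": n_components, "error": str(exc)},
        ) from exc
    dof = max(1, mask.sum() - 3 * n_components)
    tcrit = stats.t.ppf(0.975, dof)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    fits = []
    for i in range(n_components):
        a, c, s = popt[3 * i : 3 * i + 3]
        se = perr[3 * i]
        if not np.isfinite(se):
            se = 0.0
        fits.append(
            PeakFit(
                center=float(c),
                width=float(abs(s)),
                amplitude=float(a),
                amplitude_ci95=(float(a - tcrit * se), float(a + tcrit * se)),
            )
        )
    return sorted(fits, key=lambda f: f.center)


def natural_abundance_fraction(
    n_labeled: int, n_natural_sites: int, abundance: float = NATURAL_ABUNDANCE_C13
) -> float:
    """Fraction of observed signal from natural-abundance background spins.

    For one enriched site among ``n_natural_sites`` chemically overlapping
    unenriched carbons, f_na = n*a / (n_labeled + n*a).  The Q11 backbone
    carbonyl case (1 labeled + 10 natural carbonyls at 1.1%) gives ~0.099.
    """
    if not 0 <= abundance < 1:
        raise ValueError("abundance must be in [0, 1)")
    if n_labeled < 1 or n_natural_sites < 0:
        raise ValueError("need >= 1 labeled site and >= 0 natural sites")
    background = n_natural_sites * abundance
    return background / (n_labeled + background)


def natural_abundance_correction(
    curve: DephasingCurve, f_na: float
) -> DephasingCurve:
    """Remove a non-dephasing natural-abundance background from an S/S0 curve.

    Models background spins as a constant contribution f_na to the observed
    signal: E_obs = f_na + (1 - f_na) * E_true, inverted exactly as
    E_true = (E_obs - f_na) / (1 - f_na).  Values outside [-0.05, 1.05]
    after correction are clipped, with a warning reporting how many.
    """
    if not 0 <= f_na < 1:
        raise ValueError("f_na must be in [0, 1)")
    if curve.convention != "S_over_S0":
        raise ValueError("natural-abundance correction applies to S/S0 curves")
    corrected = (curve.values - f_na) / (1.0 - f_na)
    n_clip = int(np.sum((corrected < -0.05) | (corrected > 1.05)))
    if n_clip:
        warnings.warn(f"natural-abundance correction clipped {n_clip} points")
        corrected = np.clip(corrected, -0.05, 1.05)
    return DephasingCurve(curve.times, corrected, "S_over_S0", strict=curve.strict)


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------


def _solve_simplex_ls(bmat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact min ||y - B p||^2 s.t. 0 <= p <= 1, sum(p) <= 1.

    Enumerates active sets of the convex QP (K is small); the optimum is
    the feasible candidate with the lowest objective.
    """
    kdim = bmat.shape[1]
    if kdim == 1:
        b = bmat[:, 0]
        denom = float(b @ b)
        p_free = float(b @ y) / denom if denom > 0 else 0.0
        return np.array([min(1.0, max(0.0, p_free))])
    best_p, best_obj = None, np.inf
    for assignment in itertools.product((None, 0.0, 1.0), repeat=kdim):
        free = [i for i, v in enumerate(assignment) if v is None]
        fixed = np.array([0.0 if v is None else v for v in assignment])
        for sum_active in (False, True):
            target = y - bmat @ fixed
            if free:
                bf = bmat[:, free]
                if sum_active:
                    # KKT system for equality sum(p_free) = 1 - sum(fixed)
                    rhs_sum = 1.0 - fixed.sum()
                    gram = bf.T @ bf
                    kkt = np.zeros((len(free) + 1, len(free) + 1))
                    kkt[: len(free), : len(free)] = gram
                    kkt[: len(free), -1] = 1.0
                    kkt[-1, : len(free)] = 1.0
                    rhs = np.concatenate([bf.T @ target, [rhs_sum]])
                    try:
                        sol = np.linalg.solve(kkt, rhs)
                    except np.linalg.LinAlgError:
                        continue
                    p_free = sol[: len(free)]
                else:
                    p_free, *_ = np.linalg.lstsq(bf, target, rcond=None)
                p = fixed.copy()
                p[free] = p_free
            else:
                if sum_active and abs(fixed.sum() - 1.0) > 1e-12:
                    continue
                p = fixed
            if np.any(p < -1e-10) or np.any(p > 1.0 + 1e-10) or p.sum() > 1.0 + 1e-10:
                continue
            p = np.clip(p, 0.0, 1.0)
            resid = y - bmat @ p
            obj = float(resid @ resid)
            if obj < best_obj - 1e-15:
                best_obj, best_p = obj, p
    return best_p


def fit_mixture(
    data: DephasingCurve,
    bases: list[DephasingCurve],
    include_uncoupled: bool = True,
    basis_names: list[str] | None = None,
    n_bootstrap: int = 1000,
    seed: int = BOOTSTRAP_SEED,
) -> MixtureFitResult:
    """Estimate population fractions by constrained least squares.

    All curves must share one time grid (use :func:`interpolate_curve`
    first).  Curves are compared in the Delta S/S0 convention, in which the
    uncoupled remainder is the all-zero line; with ``include_uncoupled``
    False the fractions are constrained to sum to exactly 1.  95% CIs are
    percentile intervals from a residual bootstrap with a fixed seed.
    """
    if not bases:
        raise ValueError("need at least one basis curve")
    d = data.as_delta()
    bs = [b.as_delta() for b in bases]
    for b in bs:
        if not d.same_grid(b):
            raise GridError("data and basis curves must share one time grid")
    bmat = np.column_stack([b.values for b in bs])
    y = d.values
    kdim = bmat.shape[1]
    if kdim > 6:
        raise ValueError("more than 6 basis curves is not supported")
    if kdim > 1:
        sv = np.linalg.svd(bmat, compute_uv=False)
        if sv[-1] <= 1e-10 * sv[0]:
            raise ConditioningError("basis curves are numerically linearly dependent")
    names = tuple(
        basis_names
        if basis_names is not None
        else [f"basis_{i}" for i in range(kdim)]
    )

    def solve(target):
        if include_uncoupled:
            return _solve_simplex_ls(bmat, target)
        return _solve_sum_one(bmat, target)

    p_hat = solve(y)
    resid = y - bmat @ p_hat
    rms = float(np.sqrt(np.mean(resid**2)))

    rng = np.random.default_rng(seed)
    fitted = bmat @ p_hat
    npts = y.size
    # standard small-sample correction: fitted residuals underestimate the
    # noise scale by sqrt((n - K)/n); inflate before resampling
    resid = resid * np.sqrt(npts / max(1, npts - kdim))
    if kdim == 1 and include_uncoupled:
        # vectorized closed form for the common single-basis case
        idx = rng.integers(0, npts, size=(n_bootstrap, npts))
        ystar = fitted[None, :] + resid[idx]
        b = bmat[:, 0]
        denom = float(b @ b)
        pstar = np.clip(ystar @ b / denom, 0.0, 1.0)[:, None]
    else:
        pstar = np.empty((n_bootstrap, kdim))
        for i in range(n_bootstrap):
            ystar = fitted + resid[rng.integers(0, npts, size=npts)]
            pstar[i] = solve(ystar)
    ci = np.percentile(pstar, [2.5, 97.5], axis=0).T  # (K, 2)
    return MixtureFitResult(
        fractions=p_hat,
        fraction_ci95=ci,
        residual_rms=rms,
        basis_names=names,
        uncoupled_fraction=float(max(0.0, 1.0 - p_hat.sum())),
    )


def _solve_sum_one(bmat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact min ||y - B p||^2 s.t. 0 <= p <= 1, sum(p) = 1."""
    kdim = bmat.shape[1]
    best_p, best_obj = None, np.inf
    for assignment in itertools.product((None, 0.0, 1.0), repeat=kdim):
        free = [i for i, v in enumerate(assignment) if v is None]
        fixed = np.array([0.0 if v is None else v for v in assignment])
        if free:
            bf = bmat[:, free]
            target = y - bmat @ fixed
            gram = bf.T @ bf
            kkt = np.zeros((len(free) + 1, len(free) + 1))
            kkt[: len(free), : len(free)] = gram
            kkt[: len(free), -1] = 1.0
            kkt[-1, : len(free)] = 1.0
            rhs = np.concatenate([bf.T @ target, [1.0 - fixed.sum()]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            p = fixed.copy()
            p[free] = sol[: len(free)]
        else:
            if abs(fixed.sum() - 1.0) > 1e-12:
                continue
            p = fixed
        if np.any(p < -1e-10) or np.any(p > 1.0 + 1e-10):
            continue
        p = np.clip(p, 0.0, 1.0)
        resid = y - bmat @ p
        obj = float(resid @ resid)
        if obj < best_obj - 1e-15:
            best_obj, best_p = obj, p
    if best_p is None:
        raise ConditioningError("no feasible solution on the probability simplex")
    return best_p
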