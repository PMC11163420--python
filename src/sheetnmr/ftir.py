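"""Amide-I FTIR beta-sheet organizational index (beta-index).

Antiparallel beta-sheets split the amide-I band, adding a weak component
near 1695 cm-1 alongside the main beta-sheet band near 1625 cm-1; parallel
sheets lack the high-frequency component.  The beta-index is the ratio of
the fitted intensity of the 1693-1697 cm-1 peak to that of the
1624-1632 cm-1 peak; empirically, values below ~0.1 indicate parallel
and values above antiparallel sheet organization.

Pipeline: polynomial baseline through anchor windows outside the amide-I
band -> Savitzky-Golay smoothing -> three-Gaussian decomposition of the
amide-I region (components starting near 1625, 1650 and 1695 cm-1) ->
intensity ratio and threshold classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .analysis import FitFailureError, PeakFit

__all__ = [
    "Spectrum",
    "BetaIndexResult",
    "MissingBandError",
    "baseline_correct",
    "smooth",
    "beta_index",
    "classify_beta_index",
]

#: beta-index threshold separating parallel (<) from antiparallel (>=)
BETA_INDEX_THRESHOLD = 0.1

#: component windows of the index ratio, cm-1
HIGH_BAND_WINDOW = (1693.0, 1697.0)
LOW_BAND_WINDOW = (1624.0, 1632.0)

#: default Gaussian starting centers for the amide-I decomposition, cm-1
AMIDE_I_CENTERS = (1625.0, 1650.0, 1695.0)
CENTER_BOUND = 8.0  # cm-1 allowed shift of each component center

#: default baseline anchor windows, cm-1 (outside the amide-I band)
DEFAULT_ANCHORS = ((1580.0, 1600.0), (1710.0, 1730.0))

AMIDE_I_RANGE = (1600.0, 1700.0)


class MissingBandError(ValueError):
    """A required amide-I component could not be resolved."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled 1D trace: wavenumber (cm-1) vs absorbance."""

    wavenumber: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.wavenumber, dtype=float).ravel()
        y = np.asarray(self.absorbance, dtype=float).ravel()
        if x.shape != y.shape or x.size < 2:
            raise ValueError("spectrum needs matching wavenumber/absorbance arrays")
        if np.any(np.diff(x) <= 0):
            order = np.argsort(x)
            x, y = x[order], y[order]
        object.__setattr__(self, "wavenumber", x)
        object.__setattr__(self, "absorbance", y)

    def __len__(self) -> int:
        return self.wavenumber.size


@dataclass(frozen=True)
class BetaIndexResult:
    index: float
    high_band: PeakFit
    low_band: PeakFit
    classification: str  # "parallel" | "antiparallel"
    threshold: float = BETA_INDEX_THRESHOLD

    def __post_init__(self):
        if self.index < 0:
            raise ValueError("beta-index must be non-negative")
        expected = classify_beta_index(self.index, self.threshold)
        if self.classification != expected:
            raise ValueError("classification inconsistent with index and threshold")


def classify_beta_index(index: float, threshold: float = BETA_INDEX_THRESHOLD) -> str:
    """Parallel iff the index is strictly below the threshold."""
    return "parallel" if index < threshold else "antiparallel"


def baseline_correct(
    spectrum: Spectrum,
    anchor_windows=DEFAULT_ANCHORS,
    order: int | None = None,
) -> Spectrum:
    """Subtract a low-order polynomial through anchor-window medians.

    Each anchor window contributes one point (median wavenumber, median
    absorbance); the polynomial order defaults to n_anchors - 1 (capped at
    3).  Anchors inside the amide-I band trigger a warning.
    """
    anchors = [tuple(sorted(w)) for w in anchor_windows]
    if len(anchors) < 2:
        raise ValueError("need at least two anchor windows")
    for lo, hi in anchors:
        if hi > AMIDE_I_RANGE[0] and lo < AMIDE_I_RANGE[1]:
            warnings.warn(
                f"anchor window ({lo}, {hi}) overlaps the amide-I band",
                stacklevel=2,
            )
    x, y = spectrum.wavenumber, spectrum.absorbance
    xs, ys = [], []
    for lo, hi in anchors:
        mask = (x >= lo) & (x <= hi)
        if not mask.any():
            raise ValueError(f"anchor window ({lo}, {hi}) contains no samples")
        xs.append(np.median(x[mask]))
        ys.append(np.median(y[mask]))
    if order is None:
        order = min(len(anchors) - 1, 3)
    coeffs = np.polynomial.polynomial.polyfit(xs, ys, order)
    baseline = np.polynomial.polynomial.polyval(x, coeffs)
    return Spectrum(x, y - baseline)


def smooth(spectrum: Spectrum, window_points: int = 9, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing (symmetric moving polynomial).

    Window must be odd and at least 3; polynomial reproduction means
    linear data pass through unchanged and integrated area is preserved.
    """
    w = int(window_points)
    if w < 3 or w % 2 == 0:
        raise ValueError("window_points must be an odd integer >= 3")
    if w >= len(spectrum):
        raise ValueError("window_points must be smaller than the trace length")
    poly = min(polyorder, w - 1)
    ys = signal.savgol_filter(spectrum.absorbance, w, poly)
    return Spectrum(spectrum.wavenumber, ys)


def _fit_amide_components(spec: Spectrum) -> list[PeakFit]:
    """Three-Gaussian decomposition of the amide-I region."""
    x, y = spec.wavenumber, spec.absorbance
    mask = (x >= 1580.0) & (x <= 1720.0)
    xw, yw = x[mask], y[mask]
    scale = max(float(np.abs(yw).max()), 1e-12)
    p0, lower, upper = [], [], []
    for c in AMIDE_I_CENTERS:
        local = yw[(xw >= c - CENTER_BOUND) & (xw <= c + CENTER_BOUND)]
        a0 = max(float(local.max()) if local.size else scale * 0.1, scale * 1e-3)
        p0 += [a0, c, 8.0]
        lower += [0.0, c - CENTER_BOUND, 1.0]
        upper += [np.inf, c + CENTER_BOUND, 40.0]

    def model(xx, *theta):
        out = np.zeros_like(xx)
        for i in range(3):
            a, c, s = theta[3 * i : 3 * i + 3]
            out += a * np.exp(-0.5 * ((xx - c) / s) ** 2)
        return out

    try:
        popt, _ = optimize.curve_fit(
            model, xw, yw, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitFailureError("amide-I decomposition did not converge") from exc
    fits = []
    for i in range(3):
        a, c, s = popt[3 * i : 3 * i + 3]
        fits.append(PeakFit(float(c), float(s), float(a), (float(a), float(a))))
    return fits


def beta_index(
    spectrum: Spectrum,
    threshold: float = BETA_INDEX_THRESHOLD,
    anchor_windows=DEFAULT_ANCHORS,
    smooth_window: int = 9,
    mode: str = "height",
) -> BetaIndexResult:
    """Compute the amide-I beta-index and classify the sheet organization.

    ``mode`` selects the intensity measure: fitted Gaussian height
    (default, matching the peak-intensity definition of the index) or
    integrated component area.
    """
    x = spectrum.wavenumber
    if x.min() > 1580.0 or x.max() < 1720.0:
        raise MissingBandError("spectrum must cover 1580-1720 cm-1")
    corrected = baseline_correct(spectrum, anchor_windows)
    smoothed = smooth(corrected, smooth_window)
    comps = _fit_amide_components(smoothed)

    def component_near(window):
        lo, hi = window
        mid = 0.5 * (lo + hi)
        cands = [f for f in comps if abs(f.center - mid) <= CENTER_BOUND + 1e-9]
        if not cands:
            raise MissingBandError(f"no amide-I component near {mid:.0f} cm-1")
        return min(cands, key=lambda f: abs(f.center - mid))

    high = component_near(HIGH_BAND_WINDOW)
    low = component_near(LOW_BAND_WINDOW)
    low_val = low.area if mode == "area" else low.amplitude
    high_val = high.area if mode == "area" else high.amplitude
    if low_val <= 0:
        raise MissingBandError("no resolvable 1625 cm-1 beta-sheet band")
    idx = max(0.0, high_val / low_val)
    return BetaIndexResult(
        index=idx,
        high_band=high,
        low_band=low,
        classification=classify_beta_index(idx, threshold),
        threshold=threshold,
    )
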