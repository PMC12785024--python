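"""Smoothing, Savitzky-Golay derivatives, peak-candidate detection and
noise estimation.

These routines initialise the windowed Voigt fits; they are never the
quantitative result.  Peak candidates come from two channels: local
maxima of the lightly smoothed signal, and negative-curvature minima of
the second derivative — the latter resolves partially overlapped bands
that present as shoulders rather than distinct maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter, find_peaks

from .spectra import Spectrum, Window, extract_window

__all__ = [
    "PeakGuess",
    "savgol_smooth",
    "derivative",
    "detect_peaks",
    "estimate_noise",
    "savgol_variance_gain",
    "DEFAULT_QUIET_WINDOW",
]

#: Signal-free region between the fingerprint and X-H bands, used for
#: noise estimation by default.
DEFAULT_QUIET_WINDOW = Window(1900.0, 2250.0)


@dataclass(frozen=True)
class PeakGuess:
    """A candidate band for fit initialisation.

    center lies on the analysed grid; height is the smoothed signal above
    the local linear baseline; prominence is the detection prominence (AU).
    """

    center: float
    height: float
    prominence: float

    def __post_init__(self) -> None:
        if self.prominence < 0:
            raise ValueError("prominence must be >= 0")


def _check_savgol_args(window_pts: int, order: int) -> None:
    if window_pts % 2 == 0:
        raise ValueError(
            f"window_pts must be odd (symmetric filter), got {window_pts}"
        )
    if not 5 <= window_pts <= 9:
        raise ValueError(f"window_pts must be in [5, 9], got {window_pts}")
    if window_pts <= order:
        raise ValueError("window_pts must exceed the polynomial order")


def savgol_smooth(s: Spectrum, window_pts: int = 7, order: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing; polynomials of degree <= order pass
    unchanged away from the edges."""
    _check_savgol_args(window_pts, order)
    sm = savgol_filter(s.absorbance, window_pts, order)
    return s.with_absorbance(sm, savgol=(window_pts, order))


def derivative(s: Spectrum, order: int = 2, window_pts: int = 7,
               polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay derivative scaled by the actual grid spacing.

    Units: AU*cm for order 1, AU*cm^2 for order 2 (derivative w.r.t.
    wavenumber).  Requires a uniform grid.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    _check_savgol_args(window_pts, polyorder)
    if order > polyorder:
        raise ValueError("polyorder must be >= derivative order")
    dx = np.diff(s.wavenumbers)
    if not np.allclose(dx, dx[0], rtol=1e-6):
        raise ValueError("derivative requires a uniform wavenumber grid")
    d = savgol_filter(s.absorbance, window_pts, polyorder, deriv=order,
                      delta=float(dx[0]))
    return s.with_absorbance(d, savgol_deriv=(order, window_pts, polyorder))


def savgol_variance_gain(window_pts: int, order: int) -> float:
    """White-noise variance gain of the smoothing filter, sum(c_i^2)."""
    _check_savgol_args(window_pts, order)
    # central row of the projection matrix = response to a unit impulse
    impulse = np.zeros(2 * window_pts + 1)
    impulse[window_pts] = 1.0
    coeffs = savgol_filter(impulse, window_pts, order)
    return float(np.sum(coeffs**2))


def estimate_noise(s: Spectrum, quiet_window: Window | None = None) -> float:
    """Robust noise SD (AU) from first differences in a signal-free window.

    sigma_hat = 1.4826 * MAD(diff(A)) / sqrt(2).  Differencing removes
    smooth trends, MAD resists outliers; the sqrt(2) undoes the variance
    doubling of the difference filter.
    """
    if quiet_window is None:
        quiet_window = DEFAULT_QUIET_WINDOW
    lo, hi = s.span
    if quiet_window.hi < lo or quiet_window.lo > hi:
        raise ValueError(
            f"quiet window ({quiet_window.lo}, {quiet_window.hi}) lies outside "
            f"the spectrum span ({lo}, {hi})"
        )
    sub = extract_window(s, quiet_window)
    d = np.diff(sub.absorbance)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(
    s: Spectrum,
    w: Window | None = None,
    min_prominence: float | None = None,
    merge_tol: float = 4.0,
    smooth_window: int = 7,
) -> list[PeakGuess]:
    """Derivative-assisted peak candidates in a window, for initialisation.

    Candidates are the union of (a) prominent local maxima of the lightly
    smoothed signal and (b) negative-curvature minima of the 2nd
    Savitzky-Golay derivative, which resolve shoulders of overlapped
    bands.  Candidates closer than ``merge_tol`` (default: the 4 cm^-1
    instrument resolution) are merged keeping the larger prominence;
    equal prominences keep the lower wavenumber.  Sorted by descending
    prominence.  If ``min_prominence`` is None it defaults to 5x the
    noise estimate from the quiet window when available, else 5x a local
    robust estimate within the window.
    """
    sub = extract_window(s, w) if w is not None else s
    if min_prominence is None:
        try:
            sigma = estimate_noise(s)
        except ValueError:
            d = np.diff(sub.absorbance)
            mad = np.median(np.abs(d - np.median(d)))
            sigma = float(1.4826 * mad / np.sqrt(2.0))
        min_prominence = 5.0 * sigma
    sm = savgol_smooth(sub, smooth_window, 2)
    y = sm.absorbance
    x = sub.wavenumbers

    candidates: dict[int, float] = {}  # grid index -> prominence (AU)

    idx, props = find_peaks(y, prominence=min_prominence)
    for i, p in zip(idx, props["prominences"]):
        candidates[int(i)] = max(candidates.get(int(i), 0.0), float(p))

    # second-derivative channel: bands are minima of d2A/dnu2
    d2 = derivative(sub, order=2, window_pts=smooth_window).absorbance
    dx = float(x[1] - x[0])
    # convert the AU prominence floor to curvature units for a band of
    # roughly instrument-resolution width: |d2| apex ~ height / hwhm^2
    curv_floor = min_prominence / max(merge_tol, 2.0 * dx) ** 2
    # differentiation amplifies noise, so the channel also needs a floor
    # at 5x the robust noise level of the derivative itself
    d2_noise = 1.4826 * float(np.median(np.abs(d2 - np.median(d2))))
    floor2 = max(curv_floor, 5.0 * d2_noise)
    # height floor: only genuinely negative curvature counts (a saddle
    # between two bands is a local max of -d2 but has d2 > 0)
    idx2, props2 = find_peaks(-d2, prominence=floor2, height=floor2 / 4)
    # curvature locates, amplitude validates: a genuine shoulder carries
    # signal above the window's edge line, a noise wiggle does not
    slope0 = (y[-1] - y[0]) / (x[-1] - x[0])
    edge_line = y[0] + slope0 * (x - x[0])
    for i, p in zip(idx2, props2["prominences"]):
        if y[i] - edge_line[i] < min_prominence:
            continue
        equiv = float(p) * max(merge_tol, 2.0 * dx) ** 2  # back to AU scale
        candidates[int(i)] = max(candidates.get(int(i), 0.0), equiv)

    if not candidates:
        return []

    # merge within merge_tol: larger prominence wins; ties -> lower wavenumber
    items = sorted(candidates.items(), key=lambda kv: (-kv[1], x[kv[0]]))
    kept: list[tuple[int, float]] = []
    for i, prom in items:
        if all(abs(x[i] - x[j]) > merge_tol for j, _ in kept):
            kept.append((i, prom))

    # local baseline from window endpoints for the height estimate
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    base = y[0] + slope * (x - x[0])
    guesses = [
        PeakGuess(center=float(x[i]), height=float(y[i] - base[i]),
                  prominence=float(prom))
        for i, prom in kept
    ]
    guesses.sort(key=lambda g: (-g.prominence, g.center))
    return guesses
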