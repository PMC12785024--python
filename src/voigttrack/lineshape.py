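"""Exact Voigt/Gaussian/Lorentzian line shapes and model-comparison
statistics.

A band is parameterised by its integrated area A (AU*cm^-1), center nu0
(cm^-1), Gaussian width sigma and Lorentzian half-width-at-half-maximum
gamma (both cm^-1).  Area — not apex height — is the fitted amplitude:
it is the physically additive quantity and decorrelates from the widths
during optimisation; heights are derived.

The sigma > 0 evaluation uses the scaled complex complementary error
function (Faddeeva function):  V(nu) = A * Re[w(z)] / (sigma*sqrt(2*pi)),
z = (nu - nu0 + i*gamma) / (sigma*sqrt(2)).  sigma = 0 falls back to the
closed-form Lorentzian.  gamma here is the Lorentzian HWHM (the common
"Lorentzian gamma" convention); the Lorentzian FWHM is 2*gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import wofz

__all__ = [
    "VoigtComponent",
    "LinearBaseline",
    "InformationCriteria",
    "eval_voigt",
    "apex_height",
    "fwhm",
    "information_criteria",
]

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class VoigtComponent:
    """One spectral band: area (AU*cm^-1), center (cm^-1), Gaussian sigma
    and Lorentzian HWHM gamma (cm^-1)."""

    area: float
    center: float
    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        if self.sigma < 0 or self.gamma < 0:
            raise ValueError("widths must be >= 0")
        if self.sigma == 0 and self.gamma == 0:
            raise ValueError("degenerate profile: sigma and gamma both zero")
        if not all(
            np.isfinite(v) for v in (self.area, self.center, self.sigma, self.gamma)
        ):
            raise ValueError("component parameters must be finite")


@dataclass(frozen=True)
class LinearBaseline:
    """Linear baseline a + b*(nu - nu_ref); both coefficients unbounded."""

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("baseline coefficients must be finite")

    def __call__(self, grid: np.ndarray, nu_ref: float = 0.0) -> np.ndarray:
        return self.intercept + self.slope * (np.asarray(grid, dtype=float) - nu_ref)


@dataclass(frozen=True)
class InformationCriteria:
    """Least-squares AIC/BIC under a Gaussian residual likelihood."""

    aic: float
    bic: float
    n: int
    k: int
    rss: float


def eval_voigt(grid: np.ndarray, c: VoigtComponent) -> np.ndarray:
    """Evaluate the Voigt profile of component ``c`` on ``grid`` (AU).

    Unit normalisation: the profile integrates to ``c.area`` over the
    real line.  Pure-Lorentzian (sigma = 0) uses the closed form.
    """
    grid = np.asarray(grid, dtype=float)
    if c.sigma > 0:
        z = (grid - c.center + 1j * c.gamma) / (c.sigma * _SQRT2)
        return c.area * wofz(z).real / (c.sigma * _SQRT2PI)
    # sigma == 0: Lorentzian with HWHM gamma
    return c.area * (c.gamma / math.pi) / ((grid - c.center) ** 2 + c.gamma**2)


def apex_height(c: VoigtComponent) -> float:
    """Profile value at the band center, V(nu0) (AU)."""
    return float(eval_voigt(np.array([c.center]), c)[0])


def fwhm(c: VoigtComponent) -> float:
    """Full width at half maximum by the Olivero-Longbothum approximation.

    f approx 0.5346*f_L + sqrt(0.2166*f_L^2 + f_G^2) with f_L = 2*gamma,
    f_G = 2*sigma*sqrt(2*ln 2); accurate to ~0.02% over all mixing ratios.
    """
    f_l = 2.0 * c.gamma
    f_g = 2.0 * c.sigma * math.sqrt(2.0 * math.log(2.0))
    return 0.5346 * f_l + math.sqrt(0.2166 * f_l**2 + f_g**2)


def information_criteria(rss: float, n: int, k: int) -> InformationCriteria:
    """AIC/BIC for an unweighted least-squares fit.

    aic = n*ln(rss/n) + 2k ; bic = n*ln(rss/n) + k*ln(n).  Valid for
    comparing models fitted to the same n points.
    """
    if rss <= 0:
        raise ValueError(f"rss must be > 0, got {rss}")
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    ln_term = n * math.log(rss / n)
    return InformationCriteria(
        aic=ln_term + 2.0 * k,
        bic=ln_term + k * math.log(n),
        n=int(n),
        k=int(k),
        rss=float(rss),
    )
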