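"""Windowed bounded nonlinear least squares: <= 3 Voigt components plus a
linear baseline, with line-shape family and component-count selection.

The modelling surface follows the Model/Results idiom: build a
:class:`VoigtWindowModel` from a spectrum and a window, call ``.fit()``,
and read estimates, 1-sigma uncertainties, information criteria and a
``summary()`` off the returned :class:`VoigtFitResult`.  Thin functions
(`fit_window`, `select_family`, `select_components`,
`fit_static_references`) wrap the same machinery for pipeline use.

Constraint scheme: static reference spectra of the pure species are
fitted with centers free within a broad literature window (default
+/-25 cm^-1); the fitted positions then become tight center constraints
(default +/-7.5 cm^-1, per-band overridable) for every slice of the
reaction series.  Width bounds sigma in [1, 15] and gamma in [1, 20]
cm^-1 apply to every fit; amplitudes (areas) are non-negative.  All
bounds are enforced by the optimiser itself — parameters are never
clipped after the fact.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, linear_sum_assignment

from .lineshape import (
    InformationCriteria,
    LinearBaseline,
    VoigtComponent,
    apex_height,
    eval_voigt,
    information_criteria,
)
from .preprocess import detect_peaks, estimate_noise, savgol_smooth
from .spectra import Spectrum, Window, extract_window

__all__ = [
    "FitConstraints",
    "WindowModel",
    "VoigtWindowModel",
    "VoigtFitResult",
    "fit_window",
    "select_family",
    "select_components",
    "fit_static_references",
    "load_reference_table",
    "assign_components",
]

_FAMILIES = ("gaussian", "lorentzian", "voigt")
#: evaluation floor used when a pure family pins a width to "zero"
_WIDTH_FLOOR = 0.0


@dataclass(frozen=True)
class FitConstraints:
    """Bounds applied to every windowed fit.

    ``center_tol`` is the half-width of the allowed center interval
    around each component's reference center (cm^-1); widths follow the
    physically reasonable ranges sigma 1-15, gamma 1-20 cm^-1; areas are
    bounded below by ``area_min`` (non-negative amplitudes).
    """

    center_tol: float = 7.5
    sigma_bounds: tuple[float, float] = (1.0, 15.0)
    gamma_bounds: tuple[float, float] = (1.0, 20.0)
    area_min: float = 0.0

    def __post_init__(self) -> None:
        if self.center_tol <= 0:
            raise ValueError("center_tol must be > 0")
        for lo, hi in (self.sigma_bounds, self.gamma_bounds):
            if not lo <= hi:
                raise ValueError("width bounds must be ordered")


@dataclass(frozen=True)
class WindowModel:
    """A <= 3-component line-shape model within one spectral window."""

    window: Window
    family: str
    components: tuple[VoigtComponent, ...]
    baseline: LinearBaseline = LinearBaseline(0.0, 0.0)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if not 1 <= len(self.components) <= 3:
            raise ValueError("1 to 3 components are supported")
        for c in self.components:
            if not self.window.contains(c.center):
                raise ValueError(
                    f"component center {c.center} outside window "
                    f"({self.window.lo}, {self.window.hi})"
                )

    @property
    def nu_ref(self) -> float:
        """Baseline reference wavenumber (window midpoint, for conditioning)."""
        return 0.5 * (self.window.lo + self.window.hi)

    def predict(self, grid: np.ndarray) -> np.ndarray:
        y = self.baseline(grid, self.nu_ref)
        for c in self.components:
            y = y + eval_voigt(grid, c)
        return y


def _free_width_flags(family: str) -> tuple[bool, bool]:
    """(sigma free, gamma free) for a family."""
    return {
        "voigt": (True, True),
        "gaussian": (True, False),
        "lorentzian": (False, True),
    }[family]


class VoigtWindowModel:
    """Bounded NLS model for one spectral window.

    Parameters
    ----------
    spectrum : Spectrum
        Full (or pre-windowed) spectrum; the window is extracted here.
    window : Window
        Fitting window; must contain >= 8 grid points.
    components : sequence of VoigtComponent
        Initial components (1-3).  Centers must lie inside the window.
    family : {'voigt', 'gaussian', 'lorentzian'}
        Pure families pin the inactive width to zero.
    constraints : FitConstraints
    center_refs : sequence of float, optional
        Reference center per component around which ``center_tol``
        applies; defaults to the initial centers.
    center_tols : sequence of float, optional
        Per-component overrides of ``constraints.center_tol``.
    baseline0 : LinearBaseline, optional
        Initial baseline; defaults to a line through the window edges.
    noise_sd : float, optional
        Known/estimated noise SD (AU); estimated from the data quiet
        region if omitted and available.
    """

    def __init__(
        self,
        spectrum: Spectrum,
        window: Window,
        components,
        family: str = "voigt",
        constraints: FitConstraints | None = None,
        center_refs=None,
        center_tols=None,
        baseline0: LinearBaseline | None = None,
        noise_sd: float | None = None,
    ):
        if family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        self.constraints = constraints or FitConstraints()
        self.family = family
        self.data = extract_window(spectrum, window)
        self.window = window
        comps = tuple(components)
        if not 1 <= len(comps) <= 3:
            raise ValueError("1 to 3 components are supported")
        for c in comps:
            if not window.contains(c.center):
                raise ValueError(
                    f"initial center {c.center} outside window ({window.lo}, {window.hi})"
                )
        self.components0 = comps
        self.center_refs = (
            tuple(center_refs)
            if center_refs is not None
            else tuple(c.center for c in comps)
        )
        if len(self.center_refs) != len(comps):
            raise ValueError("one center reference per component required")
        if center_tols is None:
            center_tols = (self.constraints.center_tol,) * len(comps)
        self.center_tols = tuple(float(t) for t in center_tols)
        self.noise_sd = noise_sd
        self.nu_ref = 0.5 * (window.lo + window.hi)
        x = self.data.wavenumbers
        y = self.data.absorbance
        if baseline0 is None:
            y0 = float(np.median(y[:3]))
            y1 = float(np.median(y[-3:]))
            slope = (y1 - y0) / (x[-1] - x[0])
            mid = 0.5 * (y0 + y1)
            baseline0 = LinearBaseline(mid, slope)
        self.baseline0 = baseline0

    # -- parameter vector layout -------------------------------------------
    def _layout(self):
        """Per-component free-parameter names and the packing order."""
        sig_free, gam_free = _free_width_flags(self.family)
        names = []
        for i in range(len(self.components0)):
            names.append(f"c{i}_area")
            names.append(f"c{i}_center")
            if sig_free:
                names.append(f"c{i}_sigma")
            if gam_free:
                names.append(f"c{i}_gamma")
        names += ["b_intercept", "b_slope"]
        return names, sig_free, gam_free

    def _pack0(self):
        names, sig_free, gam_free = self._layout()
        fc = self.constraints
        x0, lo, hi = [], [], []
        for i, c in enumerate(self.components0):
            ref = self.center_refs[i]
            tol = self.center_tols[i]
            x0 += [c.area, min(max(c.center, ref - tol), ref + tol)]
            lo += [fc.area_min, ref - tol]
            hi += [np.inf, ref + tol]
            if sig_free:
                s0 = min(max(c.sigma, fc.sigma_bounds[0]), fc.sigma_bounds[1])
                x0.append(s0)
                lo.append(fc.sigma_bounds[0])
                hi.append(fc.sigma_bounds[1])
            if gam_free:
                g0 = min(max(c.gamma, fc.gamma_bounds[0]), fc.gamma_bounds[1])
                x0.append(g0)
                lo.append(fc.gamma_bounds[0])
                hi.append(fc.gamma_bounds[1])
        x0 += [self.baseline0.intercept, self.baseline0.slope]
        lo += [-np.inf, -np.inf]
        hi += [np.inf, np.inf]
        return np.array(x0, float), (np.array(lo, float), np.array(hi, float)), names

    def _unpack(self, theta: np.ndarray) -> WindowModel:
        sig_free, gam_free = _free_width_flags(self.family)
        comps = []
        j = 0
        for _ in self.components0:
            area, center = theta[j], theta[j + 1]
            j += 2
            sigma = theta[j] if sig_free else _WIDTH_FLOOR
            j += 1 if sig_free else 0
            gamma = theta[j] if gam_free else _WIDTH_FLOOR
            j += 1 if gam_free else 0
            comps.append(VoigtComponent(max(area, 0.0), center, sigma, gamma))
        baseline = LinearBaseline(theta[-2], theta[-1])
        return WindowModel(self.window, self.family, tuple(comps), baseline)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self._unpack(theta).predict(self.data.wavenumbers) - self.data.absorbance

    # -- fitting ------------------------------------------------------------
    def fit(self, seed: int = 0, max_starts: int = 3,
            ftol: float = 1e-10, xtol: float = 1e-10, gtol: float = 1e-10,
            max_nfev: int = 400) -> "VoigtFitResult":
        """Run the bounded NLS fit; deterministic given (inputs, seed).

        On non-convergence, up to ``max_starts`` restarts are tried from
        perturbed initial centers (jitter +/- tol/2, deterministic
        sub-seeds) before the result is flagged unconverged.
        """
        x0, bounds, names = self._pack0()
        n = len(self.data)
        k = len(x0)
        if n < 2 * k:
            import warnings

            warnings.warn(
                f"window has {n} points for {k} free parameters (< 2x); "
                "fit may be poorly determined",
                stacklevel=2,
            )
        best = None
        n_starts = 0
        for start in range(max_starts + 1):
            theta0 = x0.copy()
            if start > 0:
                rng = np.random.default_rng((seed * 1000003 + start) % (2**31))
                j = 0
                sig_free, gam_free = _free_width_flags(self.family)
                stride = 2 + int(sig_free) + int(gam_free)
                for i in range(len(self.components0)):
                    tol = self.center_tols[i]
                    jitter = rng.uniform(-tol / 2, tol / 2)
                    pos = i * stride + 1
                    theta0[pos] = np.clip(
                        x0[pos] + jitter, bounds[0][pos], bounds[1][pos]
                    )
                    j += stride
            res = least_squares(
                self._residuals,
                theta0,
                bounds=bounds,
                method="trf",
                ftol=ftol,
                xtol=xtol,
                gtol=gtol,
                max_nfev=max_nfev,
            )
            n_starts = start + 1
            if best is None or res.cost < best.cost:
                best = res
            if res.status > 0:
                break
        assert best is not None
        converged = best.status > 0
        model = self._unpack(best.x)
        resid = best.fun
        rss = float(np.sum(resid**2))
        noise = self.noise_sd
        if noise is None:
            try:
                noise = estimate_noise(Spectrum(
                    self.data.wavenumbers, self.data.absorbance))
            except ValueError:
                dof = max(n - k, 1)
                noise = math.sqrt(rss / dof)
        ic = information_criteria(max(rss, 1e-300), n, k)
        # 1-sigma uncertainties from the local linearisation at the optimum
        dof = max(n - k, 1)
        s2 = rss / dof
        J = best.jac
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            bse = np.full(k, np.nan)
        return VoigtFitResult(
            model=model,
            params=pd.Series(best.x, index=names),
            bse=pd.Series(bse, index=names),
            rss=rss,
            noise_sd=float(noise),
            ic=ic,
            residuals=resid,
            converged=bool(converged),
            n_starts_used=n_starts,
            data=self.data,
        )


@dataclass
class VoigtFitResult:
    """Fitted state of one window: estimates, uncertainties, diagnostics."""

    model: WindowModel
    params: pd.Series
    bse: pd.Series
    rss: float
    noise_sd: float
    ic: InformationCriteria
    residuals: np.ndarray
    converged: bool
    n_starts_used: int
    data: Spectrum

    @property
    def components(self) -> tuple[VoigtComponent, ...]:
        return self.model.components

    @property
    def rms(self) -> float:
        return math.sqrt(self.rss / len(self.residuals))

    def predict(self, grid: np.ndarray | None = None) -> np.ndarray:
        g = self.data.wavenumbers if grid is None else np.asarray(grid, float)
        return self.model.predict(g)

    def center(self, i: int) -> tuple[float, float]:
        """(fitted center, 1-sigma) of component ``i``."""
        return (
            float(self.params[f"c{i}_center"]),
            float(self.bse[f"c{i}_center"]),
        )

    def area(self, i: int) -> tuple[float, float]:
        return float(self.params[f"c{i}_area"]), float(self.bse[f"c{i}_area"])

    def summary(self) -> str:
        """Plain-text summary table in the Model/Results idiom."""
        lines = [
            "Voigt window fit",
            "=" * 64,
            f"window: [{self.model.window.lo:.1f}, {self.model.window.hi:.1f}] cm-1"
            f"   family: {self.model.family}   n: {self.ic.n}   k: {self.ic.k}",
            f"rss: {self.rss:.4e}  rms: {self.rms:.3e} AU  noise: {self.noise_sd:.3e} AU",
            f"aic: {self.ic.aic:.2f}  bic: {self.ic.bic:.2f}  "
            f"converged: {self.converged}  starts: {self.n_starts_used}",
            "-" * 64,
            f"{'comp':>4} {'center':>10} {'+/-':>8} {'area':>10} {'+/-':>8} "
            f"{'sigma':>7} {'gamma':>7} {'height':>9}",
        ]
        for i, c in enumerate(self.components):
            ce, cs = self.center(i)
            ar, asd = self.area(i)
            lines.append(
                f"{i:>4} {ce:>10.3f} {cs:>8.3f} {ar:>10.4f} {asd:>8.4f} "
                f"{c.sigma:>7.3f} {c.gamma:>7.3f} {apex_height(c):>9.5f}"
            )
        lines.append(
            f"baseline: intercept {self.params['b_intercept']:.4e} AU, "
            f"slope {self.params['b_slope']:.4e} AU/cm-1 (at window midpoint)"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers used by the pipeline
# ---------------------------------------------------------------------------


def fit_window(
    s: Spectrum,
    wm0: WindowModel,
    fc: FitConstraints | None = None,
    center_refs=None,
    center_tols=None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> VoigtFitResult:
    """Fit ``wm0`` (initial model) to the windowed data of ``s``."""
    model = VoigtWindowModel(
        s,
        wm0.window,
        wm0.components,
        family=wm0.family,
        constraints=fc,
        center_refs=center_refs,
        center_tols=center_tols,
        baseline0=wm0.baseline,
        noise_sd=noise_sd,
    )
    return model.fit(seed=seed)


def _default_components(s: Spectrum, w: Window, guesses=None,
                        sigma0: float = 3.0, gamma0: float = 3.0):
    """Initial components from peak guesses (or the window apex)."""
    sub = extract_window(s, w)
    if not guesses:
        sm = savgol_smooth(sub)
        i = int(np.argmax(sm.absorbance))
        base = min(float(sm.absorbance[0]), float(sm.absorbance[-1]))
        guesses = [
            type("G", (), {
                "center": float(sub.wavenumbers[i]),
                "height": max(float(sm.absorbance[i]) - base, 0.0),
            })()
        ]
    unit = VoigtComponent(1.0, 0.0, sigma0, gamma0)
    h0 = apex_height(unit)
    comps = []
    for g in guesses[:3]:
        area0 = max(getattr(g, "height", 0.0), 0.0) / h0
        comps.append(VoigtComponent(max(area0, 1e-12), g.center, sigma0, gamma0))
    return tuple(comps)


def select_family(
    s: Spectrum,
    w: Window,
    wm0: WindowModel | None = None,
    fc: FitConstraints | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> str:
    """Choose the line-shape family by BIC from a common initialisation.

    Gaussian, Lorentzian and Voigt fits are run from the same starting
    components; the lowest BIC wins.  Ties (Delta-BIC < 2 against the
    best) are resolved toward the family with fewer free width
    parameters, then toward Gaussian.  Non-convergent families are
    excluded; if none converge a RuntimeError is raised.
    """
    if wm0 is None:
        comps = _default_components(s, w)
        wm0 = WindowModel(w, "voigt", comps)
    results: dict[str, VoigtFitResult] = {}
    for fam in _FAMILIES:
        try:
            r = fit_window(s, replace(wm0, family=fam), fc,
                           noise_sd=noise_sd, seed=seed)
        except ValueError:
            continue
        if r.converged:
            results[fam] = r
    if not results:
        raise RuntimeError("no line-shape family fit converged")
    best_bic = min(r.ic.bic for r in results.values())
    # complexity order: gaussian and lorentzian have 1 free width per
    # component, voigt has 2; prefer simpler, then gaussian.
    rank = {"gaussian": 0, "lorentzian": 1, "voigt": 2}
    tied = [f for f, r in results.items() if r.ic.bic - best_bic < 2.0]
    return min(tied, key=lambda f: rank[f])


def select_components(
    s: Spectrum,
    w: Window,
    fc: FitConstraints | None = None,
    max_k: int = 3,
    noise_sd: float | None = None,
    guesses=None,
    family: str = "voigt",
    seed: int = 0,
) -> VoigtFitResult:
    """Choose the number of Voigt components (1-3) in a window.

    Start from k = max(1, number of detected peak guesses).  A (k+1)-th
    component is accepted only if the k-component fit leaves residual
    RMS > 3x the noise SD AND adding it improves BIC by at least 10
    (Delta-BIC <= -10); the count never exceeds ``max_k``.
    """
    fc = fc or FitConstraints()
    if guesses is None:
        guesses = detect_peaks(s, w)
    if noise_sd is None:
        try:
            noise_sd = estimate_noise(s)
        except ValueError:
            noise_sd = None
    comps = _default_components(s, w, guesses)
    k = max(1, min(len(comps), max_k))
    comps = comps[:k]
    fit = fit_window(s, WindowModel(w, family, comps), fc,
                     noise_sd=noise_sd, seed=seed)
    while len(fit.components) < max_k:
        if fit.rms <= 3.0 * fit.noise_sd:
            break
        # seed the extra component at the largest smoothed residual
        resid = fit.residuals
        sm = savgol_smooth(fit.data.with_absorbance(resid))
        i = int(np.argmax(np.abs(sm.absorbance)))
        new_center = float(fit.data.wavenumbers[i])
        unit = VoigtComponent(1.0, 0.0, 3.0, 3.0)
        new_area = max(abs(float(sm.absorbance[i])) / apex_height(unit), 1e-12)
        cand = tuple(fit.components) + (
            VoigtComponent(new_area, new_center, 3.0, 3.0),
        )
        try:
            fit2 = fit_window(s, WindowModel(w, family, cand), fc,
                              noise_sd=noise_sd, seed=seed)
        except ValueError:
            break
        if fit2.ic.bic - fit.ic.bic <= -10.0:
            fit = fit2
        else:
            break
    return fit


def assign_components(fitted_centers, reference_centers) -> list[int]:
    """Map fitted components to reference bands by nearest center.

    Hungarian assignment on |Delta center| prevents label switching when
    two fitted centers are ambiguous.  Returns, for each reference, the
    index of its fitted component.
    """
    fitted = np.asarray(fitted_centers, float)
    refs = np.asarray(reference_centers, float)
    cost = np.abs(refs[:, None] - fitted[None, :])
    rows, cols = linear_sum_assignment(cost)
    out = np.empty(len(refs), dtype=int)
    out[rows] = cols
    return out.tolist()


# ---------------------------------------------------------------------------
# static reference fitting
# ---------------------------------------------------------------------------


def load_reference_table(path: str | None = None) -> pd.DataFrame:
    """Packaged (or user) band table: species, label, literature center,
    broad search tolerance and tight tracking tolerance per band."""
    if path is None:
        ref = importlib.resources.files("voigttrack").joinpath(
            "data/reference_bands.csv"
        )
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {
        "species",
        "label",
        "literature_center_cm1",
        "search_tol_cm1",
        "track_tol_cm1",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"reference table lacks columns: {sorted(missing)}")
    return table


def fit_static_references(
    spectra: dict[str, Spectrum],
    ref_table: pd.DataFrame | None = None,
    window_pad: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Freely fit every table band in the static reference spectra.

    Each band is fitted in a window of literature center +/- (search
    tolerance + pad), jointly with any neighbouring table bands of the
    same species that fall inside the window.  A band whose smoothed
    signal never rises 5x above the noise within its search range is
    marked missing rather than fitted.  The fitted centers feed the
    per-band tracking constraints (tight tolerance from the table).
    """
    table = load_reference_table() if ref_table is None else ref_table
    rows = []
    for species, group in table.groupby("species", sort=False):
        if species not in spectra:
            continue
        s = spectra[species]
        try:
            noise = estimate_noise(s)
        except ValueError:
            noise = None
        lo_grid, hi_grid = s.span
        centers = group["literature_center_cm1"].to_numpy(float)
        for _, band in group.iterrows():
            lit = float(band["literature_center_cm1"])
            stol = float(band["search_tol_cm1"])
            w = Window(max(lit - stol - window_pad, lo_grid),
                       min(lit + stol + window_pad, hi_grid))
            rec = {
                "species": species,
                "label": band["label"],
                "literature_center_cm1": lit,
                "track_tol_cm1": float(band["track_tol_cm1"]),
            }
            try:
                sub = extract_window(s, w)
            except ValueError:
                rows.append({**rec, "missing": True})
                continue
            band_noise = noise
            if band_noise is None:
                d = np.diff(sub.absorbance)
                mad = np.median(np.abs(d - np.median(d)))
                band_noise = float(1.4826 * mad / math.sqrt(2.0))
            # presence check within the search range only
            sm = savgol_smooth(sub)
            x = sub.wavenumbers
            in_range = (x >= lit - stol) & (x <= lit + stol)
            edge = min(float(sm.absorbance[0]), float(sm.absorbance[-1]))
            peak_height = float(np.max(sm.absorbance[in_range]) - edge)
            if band_noise > 0 and peak_height < 5.0 * band_noise:
                rows.append({**rec, "missing": True})
                continue
            # joint fit with same-species neighbours inside the window
            neighbours = [
                c for c in centers if w.contains(c) and abs(c - lit) > 1e-9
            ]
            all_centers = [lit] + neighbours[:2]
            comps = []
            unit = VoigtComponent(1.0, 0.0, 3.0, 3.0)
            h0 = apex_height(unit)
            for c in all_centers:
                i = int(np.argmin(np.abs(x - c)))
                a0 = max(float(sm.absorbance[i]) - edge, band_noise) / h0
                comps.append(VoigtComponent(a0, c, 3.0, 3.0))
            fit = fit_window(
                s,
                WindowModel(w, "voigt", tuple(comps)),
                FitConstraints(center_tol=stol),
                center_refs=all_centers,
                noise_sd=band_noise,
                seed=seed,
            )
            c0, c0_sd = fit.center(0)
            a0_, a0_sd = fit.area(0)
            rows.append(
                {
                    **rec,
                    "missing": False,
                    "fitted_center_cm1": c0,
                    "center_sd": c0_sd,
                    "area": a0_,
                    "area_sd": a0_sd,
                    "sigma": fit.components[0].sigma,
                    "gamma": fit.components[0].gamma,
                    "converged": fit.converged,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty and "missing" not in out.columns:
        out["missing"] = False
    return out
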