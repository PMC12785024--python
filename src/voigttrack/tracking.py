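"""Per-slice independent fitting across a reaction series: trajectories,
net shifts, redistribution analysis, plateau kinetics and stability
checks.

Every time slice is fitted on its own; the only information shared
across slices is the constraint set derived from the static reference
fits.  That makes the analysis order-independent and keeps each slice's
uncertainties honest.

Model/Results surface: build a :class:`SeriesTracker` from a series, a
tracking configuration and the fitted static references, call ``.fit()``
and read trajectories, shift/plateau/stability summaries and tidy
DataFrames off the returned :class:`TrackingResults`.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from scipy.optimize import least_squares

from .lineshape import VoigtComponent, apex_height
from .peakfit import (
    FitConstraints,
    VoigtFitResult,
    WindowModel,
    fit_window,
)
from .preprocess import estimate_noise, savgol_smooth
from .spectra import SpectralSeries, Spectrum, Window, extract_window

__all__ = [
    "TrackingConfig",
    "load_tracking_config",
    "SeriesTracker",
    "TrackingResults",
    "PeakTrajectory",
    "PlateauFit",
    "RedistributionResult",
    "StabilityResult",
    "ShiftSummary",
    "track_series",
    "compute_shift",
    "fit_plateau",
    "redistribution_analysis",
    "stability_check",
    "compare_scenarios",
    "compare_summary_tables",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TrackedBand(_Strict):
    band_id: str
    ref_label: str


class TrackedWindow(_Strict):
    name: str
    lo: float
    hi: float
    bands: list[TrackedBand]

    def window(self) -> Window:
        return Window(self.lo, self.hi)


class RedistributionConfig(_Strict):
    lo: float = 1598.0
    hi: float = 1628.0
    centers: tuple[float, float] = (1606.0, 1617.0)
    center_tol_cm1: float = 2.0


class DetectionConfig(_Strict):
    smooth_window: int = 7
    smooth_order: int = 2
    merge_tol_cm1: float = 4.0
    min_prominence_sigma: float = 5.0


class TrackingConfig(_Strict):
    windows: list[TrackedWindow]
    control_band: Optional[str] = None
    control_tol_cm1: float = 1.0
    product_band: Optional[str] = None
    summary_bands: Optional[list[str]] = None
    redistribution: RedistributionConfig = RedistributionConfig()
    detection: DetectionConfig = DetectionConfig()

    def band_ids(self) -> list[str]:
        return [b.band_id for w in self.windows for b in w.bands]


def load_tracking_config(path: str | None = None) -> TrackingConfig:
    """Load a tracking config YAML; None loads the packaged default."""
    if path is None:
        ref = importlib.resources.files("voigttrack").joinpath(
            "data/tracking_default.yaml"
        )
        with importlib.resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return TrackingConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class PeakTrajectory:
    """Per-band time course of fitted parameters (1-sigma errors included)."""

    band_id: str
    times: np.ndarray
    centers: np.ndarray
    center_sds: np.ndarray
    areas: np.ndarray
    area_sds: np.ndarray
    heights: np.ndarray
    sigmas: np.ndarray
    gammas: np.ndarray
    converged: np.ndarray  # bool per slice

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_id": self.band_id,
                "time_min": self.times,
                "center_cm1": self.centers,
                "center_sd": self.center_sds,
                "area": self.areas,
                "area_sd": self.area_sds,
                "height": self.heights,
                "sigma": self.sigmas,
                "gamma": self.gammas,
                "converged": self.converged,
            }
        )


@dataclass
class PlateauFit:
    """Exponential-plateau fit A(t) = A0 + Ainf*(1 - exp(-k t))."""

    A0: float
    Ainf: float
    k: float
    t95: float
    rss: float
    valid: bool = True
    message: str = ""


@dataclass
class StabilityResult:
    band_id: str
    passed: bool
    max_excursion: float
    tol: float


@dataclass
class RedistributionResult:
    """Two-component amplitude-exchange analysis at fixed centers."""

    times: np.ndarray
    ref_centers: tuple[float, float]
    center_tol: float
    centers_lo: np.ndarray
    centers_hi: np.ndarray
    center_sds_lo: np.ndarray
    center_sds_hi: np.ndarray
    areas_lo: np.ndarray
    areas_hi: np.ndarray
    area_sds_lo: np.ndarray
    area_sds_hi: np.ndarray
    heights_lo: np.ndarray
    heights_hi: np.ndarray
    product_fraction: np.ndarray  # f(t) = A_hi / (A_lo + A_hi)
    apparent_centroid: np.ndarray
    converged: np.ndarray

    @property
    def centroid_drift(self) -> float:
        ok = self.converged
        return float(self.apparent_centroid[ok][-1] - self.apparent_centroid[ok][0])

    @property
    def max_center_motion(self) -> float:
        """Largest center excursion over slices where the center is
        actually determined.

        A component fitted with essentially zero area has no defined
        center — the estimate wanders inside its bounds — so a slice
        informs the stationarity claim only when the amplitude is
        detectable (area > 5x its 1-sigma) and the center uncertainty is
        small against the constraint box (1-sigma <= center_tol/4).
        """
        sd_cap = self.center_tol / 4.0
        motions = []
        for c, c_sd, a, a_sd in (
            (self.centers_lo, self.center_sds_lo, self.areas_lo, self.area_sds_lo),
            (self.centers_hi, self.center_sds_hi, self.areas_hi, self.area_sds_hi),
        ):
            sig = (
                self.converged
                & (a > 5.0 * np.where(np.isnan(a_sd), 0.0, a_sd))
                & (np.where(np.isnan(c_sd), np.inf, c_sd) <= sd_cap)
            )
            cc = c[sig]
            if cc.size >= 2:
                motions.append(float(np.max(np.abs(cc - cc[0]))))
        return max(motions) if motions else 0.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def compute_shift(traj: PeakTrajectory) -> tuple[float, float]:
    """Net shift Delta-nu = center(t_last) - center(t_first), converged
    endpoints only; positive = blue shift.  Returns (delta, 1-sigma)."""
    ok = np.flatnonzero(traj.converged)
    if ok.size < 2:
        raise ValueError(
            f"band {traj.band_id}: fewer than 2 converged points; no shift defined"
        )
    i, j = ok[0], ok[-1]
    delta = float(traj.centers[j] - traj.centers[i])
    sd = float(math.sqrt(traj.center_sds[i] ** 2 + traj.center_sds[j] ** 2))
    return delta, sd


def fit_plateau(times, amplitudes, noise_sd: float | None = None) -> PlateauFit:
    """Least-squares exponential-plateau fit of a band-amplitude series.

    t95 = ln(20)/k is reported as the effective completion time.  If the
    fitted rise is not significant (Ainf <= 2x noise) or the rate pins
    at its floor, a no-rise flag is returned instead of a kinetic claim.
    """
    t = np.asarray(times, float)
    a = np.asarray(amplitudes, float)
    if t.size < 5:
        raise ValueError("plateau fit needs >= 5 time points")
    if t.size != a.size:
        raise ValueError("times and amplitudes must have equal length")
    t = t - t[0]  # rate is defined from the first observation
    a0_init = float(a[0])
    ainf_init = float(a[-1] - a[0])
    # half-rise heuristic for the initial rate
    k_init = 0.2
    if abs(ainf_init) > 0:
        target = a0_init + 0.5 * ainf_init
        above = np.flatnonzero((a - target) * np.sign(ainf_init) >= 0)
        if above.size and above[0] > 0:
            t_half = t[above[0]]
            if t_half > 0:
                k_init = math.log(2.0) / t_half
    k_floor = 1e-4

    def resid(p):
        A0, Ainf, k = p
        return A0 + Ainf * (1.0 - np.exp(-k * t)) - a

    res = least_squares(
        resid,
        x0=[a0_init, ainf_init if ainf_init != 0 else 1e-6, max(k_init, k_floor)],
        bounds=([-np.inf, -np.inf, k_floor], [np.inf, np.inf, 1e3]),
        ftol=1e-12, xtol=1e-12, gtol=1e-12,
    )
    A0, Ainf, k = res.x
    rss = float(np.sum(res.fun**2))
    if noise_sd is None:
        dof = max(t.size - 3, 1)
        noise_sd = math.sqrt(rss / dof)
    if Ainf <= 2.0 * noise_sd or k <= 2.0 * k_floor:
        return PlateauFit(
            A0=float(A0), Ainf=float(Ainf), k=float(k), t95=math.inf, rss=rss,
            valid=False,
            message="no significant rise (flat or non-identifiable series)",
        )
    return PlateauFit(
        A0=float(A0), Ainf=float(Ainf), k=float(k),
        t95=float(math.log(20.0) / k), rss=rss,
    )


def stability_check(traj: PeakTrajectory, tol: float = 1.0) -> StabilityResult:
    """Drift control: pass iff max |center(t) - center(t0)| <= tol."""
    ok = traj.converged
    centers = traj.centers[ok]
    if centers.size == 0:
        return StabilityResult(traj.band_id, False, math.nan, tol)
    exc = float(np.max(np.abs(centers - centers[0])))
    return StabilityResult(traj.band_id, exc <= tol, exc, tol)


# ---------------------------------------------------------------------------
# the tracker
# ---------------------------------------------------------------------------


def _init_area(sub_sm: Spectrum, center: float, sigma0: float, gamma0: float) -> float:
    x = sub_sm.wavenumbers
    y = sub_sm.absorbance
    i = int(np.argmin(np.abs(x - center)))
    edge = min(float(np.median(y[:3])), float(np.median(y[-3:])))
    h = max(float(y[i]) - edge, 1e-6)
    return h / apex_height(VoigtComponent(1.0, 0.0, sigma0, gamma0))


class SeriesTracker:
    """Fits every slice of a reaction series under shared static-reference
    constraints.

    Parameters
    ----------
    series : SpectralSeries
    config : TrackingConfig
        Windows, band->reference mapping, control and product bands.
    references : pandas.DataFrame
        Output of :func:`voigttrack.peakfit.fit_static_references`;
        must contain one non-missing row per configured ``ref_label``.
    constraints : FitConstraints, optional
    seed : int
        Base seed for deterministic refit jitter.
    """

    def __init__(
        self,
        series: SpectralSeries,
        config: TrackingConfig | None = None,
        references: pd.DataFrame | None = None,
        constraints: FitConstraints | None = None,
        seed: int = 0,
    ):
        self.series = series
        self.config = config or load_tracking_config()
        if references is None:
            raise ValueError(
                "fitted static references are required (fit_static_references)"
            )
        self.references = references
        self.constraints = constraints or FitConstraints()
        self.seed = int(seed)
        self._ref_by_label: dict[str, pd.Series] = {}
        available = set(references["label"])
        for w in self.config.windows:
            for b in w.bands:
                if b.ref_label not in available:
                    raise KeyError(
                        f"band {b.band_id!r}: reference label {b.ref_label!r} "
                        "not present in the fitted reference table"
                    )
                row = references[references["label"] == b.ref_label].iloc[0]
                if bool(row.get("missing", False)):
                    raise ValueError(
                        f"band {b.band_id!r}: reference {b.ref_label!r} was "
                        "marked missing in the static fits"
                    )
                self._ref_by_label[b.ref_label] = row

    def fit(self) -> "TrackingResults":
        series = self.series
        cfg = self.config
        n_t = len(series)
        try:
            noise0 = estimate_noise(series.spectra[0])
        except ValueError:
            noise0 = None

        store: dict[str, dict[str, np.ndarray]] = {
            b.band_id: {
                "centers": np.full(n_t, np.nan),
                "center_sds": np.full(n_t, np.nan),
                "areas": np.full(n_t, np.nan),
                "area_sds": np.full(n_t, np.nan),
                "heights": np.full(n_t, np.nan),
                "sigmas": np.full(n_t, np.nan),
                "gammas": np.full(n_t, np.nan),
                "converged": np.zeros(n_t, dtype=bool),
            }
            for w in cfg.windows
            for b in w.bands
        }
        audit: list[dict[str, VoigtFitResult]] = [dict() for _ in range(n_t)]

        for w in cfg.windows:
            win = w.window()
            refs = [self._ref_by_label[b.ref_label] for b in w.bands]
            ref_centers = [float(r["fitted_center_cm1"]) for r in refs]
            tols = [float(r["track_tol_cm1"]) for r in refs]
            for i, s in enumerate(series.spectra):
                sub = extract_window(s, win)
                sm = savgol_smooth(sub, cfg.detection.smooth_window,
                                   cfg.detection.smooth_order)
                comps = tuple(
                    VoigtComponent(
                        _init_area(sm, c, 3.0, 3.0), c, 3.0, 3.0
                    )
                    for c in ref_centers
                )
                fit = fit_window(
                    s,
                    WindowModel(win, "voigt", comps),
                    self.constraints,
                    center_refs=ref_centers,
                    center_tols=tols,
                    noise_sd=noise0,
                    seed=self.seed * 10007 + i,
                )
                audit[i][w.name] = fit
                for j, b in enumerate(w.bands):
                    c = fit.components[j]
                    ce, ce_sd = fit.center(j)
                    ar, ar_sd = fit.area(j)
                    st = store[b.band_id]
                    st["centers"][i] = ce
                    st["center_sds"][i] = ce_sd
                    st["areas"][i] = ar
                    st["area_sds"][i] = ar_sd
                    st["heights"][i] = apex_height(c)
                    st["sigmas"][i] = c.sigma
                    st["gammas"][i] = c.gamma
                    st["converged"][i] = fit.converged

        trajectories = {
            band_id: PeakTrajectory(
                band_id=band_id,
                times=series.times.copy(),
                centers=d["centers"],
                center_sds=d["center_sds"],
                areas=d["areas"],
                area_sds=d["area_sds"],
                heights=d["heights"],
                sigmas=d["sigmas"],
                gammas=d["gammas"],
                converged=d["converged"],
            )
            for band_id, d in store.items()
        }
        return TrackingResults(
            trajectories=trajectories,
            config=cfg,
            references=self.references,
            slice_fits=audit,
            noise_sd=noise0,
        )


@dataclass
class TrackingResults:
    """Fitted state of a tracked reaction series."""

    trajectories: dict[str, PeakTrajectory]
    config: TrackingConfig
    references: pd.DataFrame
    slice_fits: list[dict[str, VoigtFitResult]] = field(repr=False, default_factory=list)
    noise_sd: float | None = None

    def __getitem__(self, band_id: str) -> PeakTrajectory:
        return self.trajectories[band_id]

    def shift(self, band_id: str) -> tuple[float, float]:
        return compute_shift(self.trajectories[band_id])

    def plateau(self, band_id: str | None = None) -> PlateauFit:
        """Exponential-plateau kinetics of the product band's fitted areas."""
        band_id = band_id or self.config.product_band
        if band_id is None:
            raise ValueError("no product band configured")
        traj = self.trajectories[band_id]
        ok = traj.converged
        return fit_plateau(traj.times[ok], traj.areas[ok])

    def stability(self) -> StabilityResult | None:
        """Drift control on the configured stability band."""
        if self.config.control_band is None:
            return None
        return stability_check(
            self.trajectories[self.config.control_band],
            tol=self.config.control_tol_cm1,
        )

    def trajectory_frame(self) -> pd.DataFrame:
        """Tidy per-slice table across all tracked bands."""
        return pd.concat(
            [t.to_frame() for t in self.trajectories.values()], ignore_index=True
        )

    def summary_frame(self) -> pd.DataFrame:
        """Per-band net-shift table (start, end, delta +/- sd)."""
        bands = self.config.summary_bands or list(self.trajectories)
        rows = []
        for band_id in bands:
            traj = self.trajectories[band_id]
            ok = np.flatnonzero(traj.converged)
            if ok.size < 2:
                rows.append({"band_id": band_id, "n_converged": int(ok.size)})
                continue
            delta, sd = compute_shift(traj)
            rows.append(
                {
                    "band_id": band_id,
                    "start_cm1": float(traj.centers[ok[0]]),
                    "start_sd": float(traj.center_sds[ok[0]]),
                    "end_cm1": float(traj.centers[ok[-1]]),
                    "end_sd": float(traj.center_sds[ok[-1]]),
                    "delta_cm1": delta,
                    "delta_sd": sd,
                    "n_converged": int(ok.size),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text report: shifts, plateau kinetics, drift control."""
        lines = ["Series tracking summary", "=" * 64]
        df = self.summary_frame()
        for _, r in df.iterrows():
            if "delta_cm1" not in r or pd.isna(r.get("delta_cm1", np.nan)):
                lines.append(f"{r['band_id']:>10}: insufficient converged fits")
                continue
            lines.append(
                f"{r['band_id']:>10}: {r['start_cm1']:9.3f} -> {r['end_cm1']:9.3f} cm-1"
                f"   delta = {r['delta_cm1']:+7.3f} +/- {r['delta_sd']:.3f} cm-1"
            )
        if self.config.product_band:
            p = self.plateau()
            if p.valid:
                lines.append(
                    f"product band {self.config.product_band}: k = {p.k:.4f} min-1, "
                    f"t95 = {p.t95:.2f} min"
                )
            else:
                lines.append(
                    f"product band {self.config.product_band}: no-rise ({p.message})"
                )
        st = self.stability()
        if st is not None:
            verdict = "PASS" if st.passed else "FAIL"
            lines.append(
                f"drift control {st.band_id}: {verdict} "
                f"(max excursion {st.max_excursion:.3f} cm-1, tol {st.tol:.2f})"
            )
        return "\n".join(lines)


def track_series(
    series: SpectralSeries,
    references: pd.DataFrame,
    config: TrackingConfig | None = None,
    constraints: FitConstraints | None = None,
    seed: int = 0,
) -> TrackingResults:
    """Functional wrapper: fit every slice under shared constraints."""
    return SeriesTracker(
        series, config=config, references=references,
        constraints=constraints, seed=seed,
    ).fit()


# ---------------------------------------------------------------------------
# redistribution analysis
# ---------------------------------------------------------------------------


def redistribution_analysis(
    series: SpectralSeries,
    w: Window | None = None,
    centers: tuple[float, float] | None = None,
    center_tol: float = 2.0,
    noise_sd: float | None = None,
    seed: int = 0,
) -> RedistributionResult:
    """Two fixed-center components exchanging intensity.

    Each slice is fitted with two Voigt components whose centers are
    constrained to +/- ``center_tol`` around the given positions, areas
    and widths free.  Reports the product fraction
    f(t) = A_hi/(A_lo + A_hi) and, per slice, the apparent single-peak
    centroid of the baseline-subtracted window — which drifts even
    though the true component centers stay put.
    """
    if w is None:
        w = Window(1575.0, 1650.0)
    if centers is None:
        centers = (1606.0, 1617.0)
    nu_lo, nu_hi = sorted(centers)
    if noise_sd is None:
        try:
            noise_sd = estimate_noise(series.spectra[0])
        except ValueError:
            noise_sd = None
    n_t = len(series)
    out = {
        name: np.full(n_t, np.nan)
        for name in (
            "centers_lo", "centers_hi", "center_sds_lo", "center_sds_hi",
            "areas_lo", "areas_hi", "area_sds_lo", "area_sds_hi",
            "heights_lo", "heights_hi", "fraction", "centroid",
        )
    }
    conv = np.zeros(n_t, dtype=bool)
    fc = FitConstraints(center_tol=center_tol)
    for i, s in enumerate(series.spectra):
        sub = extract_window(s, w)
        sm = savgol_smooth(sub)
        comps = tuple(
            VoigtComponent(_init_area(sm, c, 3.0, 3.0), c, 3.0, 3.0)
            for c in (nu_lo, nu_hi)
        )
        fit = fit_window(
            s,
            WindowModel(w, "voigt", comps),
            fc,
            center_refs=[nu_lo, nu_hi],
            center_tols=[center_tol, center_tol],
            noise_sd=noise_sd,
            seed=seed * 10007 + i,
        )
        a_lo, a_lo_sd = fit.area(0)
        a_hi, a_hi_sd = fit.area(1)
        out["centers_lo"][i], out["center_sds_lo"][i] = fit.center(0)
        out["centers_hi"][i], out["center_sds_hi"][i] = fit.center(1)
        out["areas_lo"][i] = a_lo
        out["areas_hi"][i] = a_hi
        out["area_sds_lo"][i] = a_lo_sd
        out["area_sds_hi"][i] = a_hi_sd
        out["heights_lo"][i] = apex_height(fit.components[0])
        out["heights_hi"][i] = apex_height(fit.components[1])
        tot = a_lo + a_hi
        out["fraction"][i] = a_hi / tot if tot > 0 else np.nan
        # apparent centroid of the baseline-subtracted signal
        base = fit.model.baseline(sub.wavenumbers, fit.model.nu_ref)
        sig = np.clip(sub.absorbance - base, 0.0, None)
        tot_sig = float(np.sum(sig))
        out["centroid"][i] = (
            float(np.sum(sub.wavenumbers * sig) / tot_sig) if tot_sig > 0 else np.nan
        )
        conv[i] = fit.converged
    frac = np.clip(out["fraction"], 0.0, 1.0)
    return RedistributionResult(
        times=series.times.copy(),
        ref_centers=(nu_lo, nu_hi),
        center_tol=center_tol,
        centers_lo=out["centers_lo"],
        centers_hi=out["centers_hi"],
        center_sds_lo=out["center_sds_lo"],
        center_sds_hi=out["center_sds_hi"],
        areas_lo=out["areas_lo"],
        areas_hi=out["areas_hi"],
        area_sds_lo=out["area_sds_lo"],
        area_sds_hi=out["area_sds_hi"],
        heights_lo=out["heights_lo"],
        heights_hi=out["heights_hi"],
        product_fraction=frac,
        apparent_centroid=out["centroid"],
        converged=conv,
    )


# ---------------------------------------------------------------------------
# cross-scenario comparison
# ---------------------------------------------------------------------------


@dataclass
class ShiftSummary:
    """Band x scenario shift table plus the t=0 consistency statistic."""

    table: pd.DataFrame
    t0_spread: pd.DataFrame

    def __str__(self) -> str:
        return (
            "Shift comparison (band x scenario)\n"
            + self.table.to_string(index=False)
            + "\n\nt=0 center spread per band (cm-1)\n"
            + self.t0_spread.to_string(index=False)
        )


def compare_summary_tables(tables: dict[str, pd.DataFrame]) -> ShiftSummary:
    """Cross-scenario comparison from per-scenario summary tables.

    ``t0 spread`` is, per band, the max - min of the starting centers
    across scenarios, with a propagated 1-sigma from the two extreme
    scenarios' start-center uncertainties.  A band absent from a
    scenario is recorded as absent, not fatal.
    """
    if len(tables) < 1:
        raise ValueError("at least one tracked scenario is required")
    rows = []
    for name, df in tables.items():
        for _, r in df.iterrows():
            rows.append({"scenario": name, **r.to_dict()})
    table = pd.DataFrame(rows)
    spread_rows = []
    for band_id, grp in table.groupby("band_id", sort=False):
        ok = grp.dropna(subset=["start_cm1"]) if "start_cm1" in grp else grp.iloc[0:0]
        if len(ok) < 2:
            spread_rows.append(
                {"band_id": band_id, "n_scenarios": len(ok),
                 "t0_spread_cm1": 0.0 if len(ok) == 1 else np.nan}
            )
            continue
        starts = ok["start_cm1"].to_numpy(float)
        sds = ok["start_sd"].to_numpy(float) if "start_sd" in ok else np.zeros(len(ok))
        i_max, i_min = int(np.argmax(starts)), int(np.argmin(starts))
        spread = float(starts[i_max] - starts[i_min])
        spread_sd = float(math.sqrt(sds[i_max] ** 2 + sds[i_min] ** 2))
        spread_rows.append(
            {
                "band_id": band_id,
                "n_scenarios": len(ok),
                "t0_spread_cm1": spread,
                "t0_spread_sd": spread_sd,
            }
        )
    return ShiftSummary(table=table, t0_spread=pd.DataFrame(spread_rows))


def compare_scenarios(results: dict[str, TrackingResults]) -> ShiftSummary:
    """Cross-scenario shift comparison from tracked results."""
    return compare_summary_tables(
        {name: res.summary_frame() for name, res in results.items()}
    )
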