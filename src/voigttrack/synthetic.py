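"""Scenario-driven generator of static reference spectra and reaction
series with exact ground truth.

The study's raw measurements are not publicly archived, so validation
rests on synthetic data whose statistical structure emulates kinetic
ATR-FTIR acquisitions of alkaline-phosphatase (ALP) catalysed PNPP
hydrolysis: multi-band Voigt spectra on 400-4000 cm^-1 grids (0.25 cm^-1
static / 0.5 cm^-1 kinetic spacing), 1.5 min time resolution over
0-33 min, first-order substrate-to-product conversion, additive white
noise and per-slice linear baseline drift.

Band motion follows an exponential approach sharing the conversion rate
k (min^-1):

    nu(t) = nu_end - (nu_end - nu_start) * exp(-k t)
    A(t)  = A_end  - (A_end  - A_start)  * exp(-k t)

so a product band with A_start = A0 and A_end = A0 + Ainf rises as
A0 + Ainf*(1 - exp(-k t)) and reaches 95% of its plateau at
t95 = ln(20)/k.

Three packaged scenarios (high/mid/low enzyme loading) encode the
tracked-band endpoints of the study conditions; their ground truth is
what the analysis pipeline is graded against.
"""

from __future__ import annotations

import importlib.resources
import math
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .lineshape import VoigtComponent, eval_voigt
from .peakfit import load_reference_table
from .spectra import Spectrum, SpectralSeries

__all__ = [
    "BandTrajectorySpec",
    "EnvelopeSpec",
    "Scenario",
    "generate_static",
    "generate_series",
    "generate_blank",
    "load_scenario",
    "save_scenario",
    "load_packaged_scenario",
    "packaged_scenario_names",
    "LN20",
]

LN20 = math.log(20.0)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSpec(_Strict):
    lo: float = 400.0
    hi: float = 4000.0
    spacing: float = 0.5

    @model_validator(mode="after")
    def _check(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.lo >= self.hi:
            raise ValueError("grid requires lo < hi")
        return self

    def axis(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.spacing)) + 1
        return self.lo + self.spacing * np.arange(n)


class TimeSpec(_Strict):
    t0: float = 0.0
    t_end: float = 33.0
    step: float = 1.5

    @model_validator(mode="after")
    def _check(self):
        if self.step <= 0:
            raise ValueError("time step must be > 0")
        if self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")
        return self

    def axis(self) -> np.ndarray:
        n = int(math.floor((self.t_end - self.t0) / self.step + 1e-9)) + 1
        return self.t0 + self.step * np.arange(n)


class DriftSpec(_Strict):
    """Per-slice linear baseline drift: slope and intercept drawn i.i.d.
    uniform within +/- the stated maxima."""

    slope_max: float = 1.0e-6  # AU per cm^-1
    intercept_max: float = 1.0e-4  # AU


class BandTrajectorySpec(_Strict):
    """One band's ground-truth trajectory (fit-able: widths within the
    fit bounds)."""

    band_id: str
    center_start: float
    center_end: float
    area_start: float = Field(ge=0.0)
    area_end: float = Field(ge=0.0)
    sigma: float = 3.5
    gamma: float = 3.0
    rate_k: Optional[float] = None  # min^-1; None = use the scenario rate

    @model_validator(mode="after")
    def _check(self):
        if not 1.0 <= self.sigma <= 15.0:
            raise ValueError(
                f"band {self.band_id}: sigma {self.sigma} outside fit bounds [1, 15]"
            )
        if not 1.0 <= self.gamma <= 20.0:
            raise ValueError(
                f"band {self.band_id}: gamma {self.gamma} outside fit bounds [1, 20]"
            )
        if self.rate_k is not None and self.rate_k <= 0:
            raise ValueError(f"band {self.band_id}: rate_k must be > 0")
        return self

    def center_at(self, t: np.ndarray, k: float) -> np.ndarray:
        kk = self.rate_k if self.rate_k is not None else k
        return self.center_end - (self.center_end - self.center_start) * np.exp(
            -kk * t
        )

    def area_at(self, t: np.ndarray, k: float) -> np.ndarray:
        kk = self.rate_k if self.rate_k is not None else k
        return self.area_end - (self.area_end - self.area_start) * np.exp(-kk * t)


class EnvelopeSpec(_Strict):
    """Broad background feature (e.g. the X-H stretching envelope).

    Present for realism only; exempt from the fit-width bounds and never
    a fitting target.
    """

    center: float
    area: float = Field(ge=0.0)
    sigma: float = 110.0
    gamma: float = 0.0


class Scenario(_Strict):
    """Full specification of one synthetic reaction experiment."""

    name: str
    metadata: dict = Field(default_factory=dict)
    grid: GridSpec = GridSpec()
    times: TimeSpec = TimeSpec()
    rate_k: float = Field(gt=0.0)
    noise_sd: float = Field(default=2.0e-4, ge=0.0)
    drift: DriftSpec = DriftSpec()
    bands: list[BandTrajectorySpec]
    envelopes: list[EnvelopeSpec] = Field(default_factory=list)
    buffer_bands: list[EnvelopeSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self):
        for b in self.bands:
            for c in (b.center_start, b.center_end):
                if not self.grid.lo <= c <= self.grid.hi:
                    raise ValueError(
                        f"band {b.band_id}: center {c} outside grid "
                        f"[{self.grid.lo}, {self.grid.hi}]"
                    )
        ids = [b.band_id for b in self.bands]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate band_id in scenario")
        return self

    @property
    def t95(self) -> float:
        """Time to 95% of plateau for the shared conversion rate."""
        return LN20 / self.rate_k


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _sum_envelopes(grid: np.ndarray, envelopes) -> np.ndarray:
    y = np.zeros_like(grid)
    for e in envelopes:
        if e.area <= 0:
            continue
        y += eval_voigt(grid, VoigtComponent(e.area, e.center, e.sigma, e.gamma))
    return y


def generate_series(sc: Scenario, seed: int = 0):
    """Simulate a reaction series; returns (SpectralSeries, truth record).

    Per slice: sum of band Voigts at their time-dependent centers/areas,
    plus static envelopes and buffer bands, plus a per-slice linear
    baseline drift, plus i.i.d. Gaussian noise.  Bit-identical for equal
    (scenario, seed).
    """
    rng = np.random.default_rng(seed)
    grid = sc.grid.axis()
    t = sc.times.axis()
    env = _sum_envelopes(grid, sc.envelopes) + _sum_envelopes(grid, sc.buffer_bands)
    nu_mid = 0.5 * (grid[0] + grid[-1])
    spectra = []
    truth_bands: dict[str, dict] = {
        b.band_id: {
            "centers": b.center_at(t, sc.rate_k),
            "areas": b.area_at(t, sc.rate_k),
            "center_start": b.center_start,
            "center_end": b.center_end,
            "area_start": b.area_start,
            "area_end": b.area_end,
            "sigma": b.sigma,
            "gamma": b.gamma,
            "delta_nu": float(
                b.center_at(t[-1:], sc.rate_k)[0] - b.center_at(t[:1], sc.rate_k)[0]
            ),
            "rate_k": b.rate_k if b.rate_k is not None else sc.rate_k,
        }
        for b in sc.bands
    }
    slopes = rng.uniform(-sc.drift.slope_max, sc.drift.slope_max, size=t.size)
    intercepts = rng.uniform(
        -sc.drift.intercept_max, sc.drift.intercept_max, size=t.size
    )
    for i, ti in enumerate(t):
        y = env.copy()
        for b in sc.bands:
            c = float(b.center_at(np.array([ti]), sc.rate_k)[0])
            a = float(b.area_at(np.array([ti]), sc.rate_k)[0])
            if a > 0:
                y += eval_voigt(grid, VoigtComponent(a, c, b.sigma, b.gamma))
        y += intercepts[i] + slopes[i] * (grid - nu_mid)
        if sc.noise_sd > 0:
            y += rng.normal(0.0, sc.noise_sd, size=grid.size)
        spectra.append(
            Spectrum(grid, y, {"scenario": sc.name, "time_min": float(ti)})
        )
    series = SpectralSeries(t, tuple(spectra))
    truth = {
        "scenario": sc.name,
        "seed": int(seed),
        "rate_k": sc.rate_k,
        "t95": sc.t95,
        "noise_sd": sc.noise_sd,
        "times": t,
        "bands": truth_bands,
    }
    return series, truth


def generate_blank(sc: Scenario, seed: int = 0) -> Spectrum:
    """Buffer-only spectrum on the scenario grid (own noise draw)."""
    rng = np.random.default_rng(seed)
    grid = sc.grid.axis()
    y = _sum_envelopes(grid, sc.buffer_bands)
    if sc.noise_sd > 0:
        y = y + rng.normal(0.0, sc.noise_sd, size=grid.size)
    return Spectrum(grid, y, {"scenario": sc.name, "blank": True})


_DEFAULT_ENVELOPES = {
    # broad O-H / N-H stretching envelopes; PNPP is largely featureless
    # in the X-H region and gets none.
    "ALP": [EnvelopeSpec(center=3380.0, area=8.0)],
    "PNP": [EnvelopeSpec(center=3400.0, area=6.0)],
    "Pi": [EnvelopeSpec(center=3350.0, area=6.0)],
    "PNPP": [],
}


def generate_static(
    species: str,
    seed: int = 0,
    ref_table=None,
    bands=None,
    spacing: float = 0.25,
    grid_lo: float = 400.0,
    grid_hi: float = 4000.0,
    noise_sd: float = 1.0e-4,
    default_area: float = 0.30,
    sigma: float = 3.5,
    gamma: float = 3.0,
    include_context: bool = True,
    envelopes=None,
):
    """Synthesize a static reference spectrum; returns (Spectrum, truth).

    Bands default to the packaged reference-table rows for ``species``
    (context rows included unless ``include_context=False``), each a
    Voigt of ``default_area`` with the default sharp widths, plus a
    broad species-appropriate X-H envelope.  Static acquisitions average
    more scans than kinetic ones, hence the lower default noise.
    """
    grid = GridSpec(lo=grid_lo, hi=grid_hi, spacing=spacing).axis()
    if bands is None:
        table = load_reference_table() if ref_table is None else ref_table
        sub = table[table["species"] == species]
        if sub.empty:
            raise ValueError(f"species {species!r} not in the reference table")
        if not include_context and "role" in sub.columns:
            sub = sub[sub["role"] == "primary"]
        bands = [
            {"center": float(r["literature_center_cm1"]), "area": default_area,
             "sigma": sigma, "gamma": gamma, "label": r["label"]}
            for _, r in sub.iterrows()
        ]
    comps = []
    for b in bands:
        c = VoigtComponent(b["area"], b["center"], b.get("sigma", sigma),
                           b.get("gamma", gamma))
        if not grid_lo <= c.center <= grid_hi:
            raise ValueError(f"band at {c.center} cm^-1 outside the grid")
        comps.append(c)
    if envelopes is None:
        envelopes = _DEFAULT_ENVELOPES.get(species, [])
    rng = np.random.default_rng(seed)
    y = _sum_envelopes(grid, envelopes)
    for c in comps:
        y += eval_voigt(grid, c)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=grid.size)
    truth = {
        "species": species,
        "seed": int(seed),
        "noise_sd": noise_sd,
        "bands": [
            {"center": c.center, "area": c.area, "sigma": c.sigma, "gamma": c.gamma}
            for c in comps
        ],
    }
    return Spectrum(grid, y, {"species": species, "synthetic": True}), truth


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------


def load_scenario(path: str) -> Scenario:
    """Load and schema-validate a scenario YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must contain a mapping")
    return Scenario.model_validate(raw)


def save_scenario(sc: Scenario, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sc.model_dump(), fh, sort_keys=False)


def packaged_scenario_names() -> list[str]:
    root = importlib.resources.files("voigttrack").joinpath("data/scenarios")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_packaged_scenario(name: str) -> Scenario:
    """Load one of the packaged scenarios: high_alp, mid_alp, low_alp."""
    ref = importlib.resources.files("voigttrack").joinpath(
        f"data/scenarios/{name}.yaml"
    )
    with importlib.resources.as_file(ref) as p:
        if not p.exists():
            raise FileNotFoundError(
                f"no packaged scenario {name!r}; available: "
                f"{packaged_scenario_names()}"
            )
        return load_scenario(str(p))
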