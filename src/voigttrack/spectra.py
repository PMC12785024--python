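"""Domain containers and I/O for absorbance spectra and time-resolved series.

A :class:`Spectrum` is a single absorbance trace A(nu) on a strictly
ascending wavenumber grid (cm^-1).  A :class:`SpectralSeries` is a
time-ordered collection of spectra sharing one grid exactly, as produced
by a kinetic ATR-FTIR acquisition.  Files exported by spectrometers are
frequently ordered high-to-low wavenumber; everything here is normalised
to ascending order on read, and only plotting may reverse the axis.

Supported formats are deliberately narrow: two-column delimited text
(comma or tab, optional single header line) and a minimal JCAMP-DX 4.24
subset (AFFN ``(X++(Y..Y))`` XYDATA only).  Anything else raises rather
than risking a silent mis-parse.
"""

from __future__ import annotations

import csv as _csv
import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralSeries",
    "Window",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "subtract_blank",
    "extract_window",
    "read_series_manifest",
    "write_series_manifest",
    "read_series_wide",
    "write_series_wide",
]


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed unambiguously."""


@dataclass(frozen=True)
class Window:
    """Closed wavenumber interval [lo, hi] in cm^-1 used for windowed fitting."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise ValueError("window bounds must be finite")
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got ({self.lo}, {self.hi})")

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace: strictly ascending wavenumbers (cm^-1) vs AU.

    Absorbance may be negative (difference spectra legitimately go below
    zero after blank subtraction).  Both arrays are defensive read-only
    copies; ``metadata`` is free-form provenance.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D")
        if wn.size != ab.size:
            raise ValueError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbance values"
            )
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wn)) or not np.all(np.isfinite(ab)):
            raise ValueError("non-finite values in spectrum")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        wn.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def with_absorbance(self, values: np.ndarray, **meta) -> "Spectrum":
        """Same grid, new absorbance; merges ``meta`` into the metadata."""
        return Spectrum(self.wavenumbers, values, {**self.metadata, **meta})


@dataclass(frozen=True)
class SpectralSeries:
    """Time-ordered spectra on one shared grid.

    ``times`` are minutes; the first entry defines t = 0 of the reaction
    record.  The constructor sorts (time, spectrum) pairs by time, then
    requires strictly increasing times and bit-identical grids.
    """

    times: np.ndarray
    spectra: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        spectra = tuple(self.spectra)
        if t.ndim != 1 or t.size != len(spectra):
            raise ValueError("times and spectra must have matching lengths")
        if t.size < 2:
            raise ValueError("a series needs at least 2 time points")
        order = np.argsort(t, kind="stable")
        t = t[order]
        spectra = tuple(spectra[i] for i in order)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing (duplicates found)")
        grid = spectra[0].wavenumbers
        for i, s in enumerate(spectra[1:], start=1):
            if s.wavenumbers.shape != grid.shape or not np.array_equal(
                s.wavenumbers, grid
            ):
                raise ValueError(
                    f"spectrum at index {i} is not on the shared wavenumber grid"
                )
        t.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "spectra", spectra)

    def __len__(self) -> int:
        return self.times.size

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def absorbance_matrix(self) -> np.ndarray:
        """(n_times, n_points) matrix of absorbance values."""
        return np.vstack([s.absorbance for s in self.spectra])


# ---------------------------------------------------------------------------
# single-spectrum I/O
# ---------------------------------------------------------------------------


def _read_csv_spectrum(path: str) -> Spectrum:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SpectrumParseError(f"{path}: empty file")
    # sniff delimiter: prefer tab if present, else comma
    delim = "\t" if "\t" in lines[0] or (len(lines) > 1 and "\t" in lines[1]) else ","
    rows: list[tuple[float, float]] = []
    start = 0
    # optional single header line
    first = lines[0].split(delim)
    try:
        float(first[0])
    except ValueError:
        start = 1
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        parts = [p.strip() for p in ln.split(delim)]
        if len(parts) < 2:
            raise SpectrumParseError(
                f"{path}: line {lineno}: expected two delimited columns, got {ln!r}"
            )
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise SpectrumParseError(
                f"{path}: line {lineno}: non-numeric row {ln!r}"
            ) from exc
        rows.append((x, y))
    arr = np.array(rows, dtype=float)
    return _from_unordered(arr[:, 0], arr[:, 1], {"source": os.fspath(path)})


def _from_unordered(wn: np.ndarray, ab: np.ndarray, meta: dict) -> Spectrum:
    order = np.argsort(wn, kind="stable")
    wn, ab = wn[order], ab[order]
    if np.any(np.diff(wn) <= 0):
        raise ValueError("wavenumber axis contains duplicate values")
    return Spectrum(wn, ab, meta)


def _read_jcamp_spectrum(path: str) -> Spectrum:
    """Minimal JCAMP-DX 4.24 reader: AFFN ``(X++(Y..Y))`` XYDATA only.

    Compressed ordinate dialects (SQZ/DIF/DUP/PAC) raise an explicit
    unsupported-dialect error instead of being mis-decoded.
    """
    meta: dict = {"source": os.fspath(path)}
    xfactor = yfactor = 1.0
    in_data = False
    xs: list[float] = []
    ys: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "TITLE":
                    meta["title"] = value
                elif key == "XUNITS":
                    meta["xunits"] = value
                elif key == "YUNITS":
                    meta["yunits"] = value
                elif key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "XYDATA":
                    if value.replace(" ", "") != "(X++(Y..Y))":
                        raise SpectrumParseError(
                            f"{path}: unsupported XYDATA dialect {value!r}; "
                            "only AFFN (X++(Y..Y)) is supported"
                        )
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if not in_data:
                continue
            tokens = line.replace(",", " ").split()
            for tok in tokens:
                # AFFN tokens are plain numbers; anything else is a
                # compressed-form character we refuse to guess at.
                try:
                    float(tok)
                except ValueError as exc:
                    raise SpectrumParseError(
                        f"{path}: line {lineno}: non-AFFN token {tok!r} "
                        "(compressed JCAMP forms are unsupported)"
                    ) from exc
            vals = [float(t) for t in tokens]
            if len(vals) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: XYDATA line with fewer than 2 values"
                )
            x0 = vals[0] * xfactor
            yvals = [v * yfactor for v in vals[1:]]
            xs.append(x0)
            ys.append(yvals)  # type: ignore[arg-type]
    if not xs:
        raise SpectrumParseError(f"{path}: no XYDATA records found")
    # expand per-line x: successive y values advance by the implied spacing
    all_x: list[float] = []
    all_y: list[float] = []
    for i, (x0, yrow) in enumerate(zip(xs, ys)):
        if i + 1 < len(xs) and len(yrow) > 1:
            dx = (xs[i + 1] - x0) / len(yrow)
        elif i > 0 and len(yrow) > 1:
            dx = (x0 - xs[i - 1]) / len(ys[i - 1])
        else:
            dx = 0.0
        for j, y in enumerate(yrow):
            all_x.append(x0 + j * dx)
            all_y.append(y)
    return _from_unordered(np.array(all_x), np.array(all_y), meta)


def read_spectrum(path: str, format: str | None = None) -> Spectrum:
    """Read a spectrum from ``path``; ``format`` in {'csv', 'jcamp'} or inferred.

    The returned spectrum is always ascending in wavenumber regardless of
    file order.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "jcamp" if ext in {".jdx", ".dx", ".jcm"} else "csv"
    if format == "csv":
        return _read_csv_spectrum(path)
    if format == "jcamp":
        return _read_jcamp_spectrum(path)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'jcamp'")


def write_spectrum(s: Spectrum, path: str, format: str | None = None) -> None:
    """Write ``s`` as two-column csv or minimal JCAMP-DX (AFFN XYDATA)."""
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "jcamp" if ext in {".jdx", ".dx", ".jcm"} else "csv"
    if format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["wavenumber_cm1", "absorbance_au"])
            for x, y in zip(s.wavenumbers, s.absorbance):
                w.writerow([f"{x:.10g}", f"{y:.10g}"])
        return
    if format == "jcamp":
        buf = io.StringIO()
        buf.write(f"##TITLE={s.metadata.get('title', 'voigttrack spectrum')}\n")
        buf.write("##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
        buf.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
        buf.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
        buf.write(f"##FIRSTX={s.wavenumbers[0]:.10g}\n")
        buf.write(f"##LASTX={s.wavenumbers[-1]:.10g}\n")
        buf.write(f"##NPOINTS={len(s)}\n")
        buf.write("##XYDATA=(X++(Y..Y))\n")
        for x, y in zip(s.wavenumbers, s.absorbance):
            buf.write(f"{x:.10g} {y:.10g}\n")
        buf.write("##END=\n")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
        return
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'jcamp'")


# ---------------------------------------------------------------------------
# grid operations
# ---------------------------------------------------------------------------


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation of ``s`` onto ``grid`` (must lie within the span).

    Needed because static acquisitions (0.25 cm^-1 spacing) and kinetic
    acquisitions (0.5 cm^-1) live on different grids.  Extrapolation is
    refused.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.span
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"resample target [{grid[0]}, {grid[-1]}] extends beyond source span "
            f"[{lo}, {hi}]; extrapolation is not supported"
        )
    ab = np.interp(grid, s.wavenumbers, s.absorbance)
    return Spectrum(grid, ab, {**s.metadata, "resampled": True})


def subtract_blank(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Pointwise sample - blank; the blank is resampled onto the sample grid.

    Removes buffer/solvent absorbance and session baseline.  Negative
    results are preserved (difference spectra legitimately go negative).
    """
    if np.array_equal(sample.wavenumbers, blank.wavenumbers):
        b = blank
    else:
        lo, hi = blank.span
        if sample.wavenumbers[0] < lo or sample.wavenumbers[-1] > hi:
            raise ValueError(
                "blank span does not cover the sample grid; cannot subtract"
            )
        b = resample(blank, sample.wavenumbers)
    return sample.with_absorbance(
        sample.absorbance - b.absorbance,
        blank=blank.metadata.get("source", "<in-memory blank>"),
    )


def extract_window(s: Spectrum, w: Window) -> Spectrum:
    """Sub-spectrum on [w.lo, w.hi], inclusive; requires >= 8 grid points."""
    mask = (s.wavenumbers >= w.lo) & (s.wavenumbers <= w.hi)
    n = int(mask.sum())
    if n < 8:
        raise ValueError(
            f"window ({w.lo}, {w.hi}) contains only {n} grid points; "
            ">= 8 are required for fitting"
        )
    return Spectrum(s.wavenumbers[mask], s.absorbance[mask], dict(s.metadata))


# ---------------------------------------------------------------------------
# series I/O: manifest + per-time files, or one wide table
# ---------------------------------------------------------------------------


def read_series_manifest(path: str) -> SpectralSeries:
    """Read a series from a manifest csv with columns ``time_min,path``.

    Relative spectrum paths are resolved against the manifest directory.
    """
    base = os.path.dirname(os.path.abspath(path))
    man = pd.read_csv(path)
    for col in ("time_min", "path"):
        if col not in man.columns:
            raise SpectrumParseError(f"{path}: manifest lacks required column {col!r}")
    times, spectra = [], []
    for _, row in man.iterrows():
        p = str(row["path"])
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        times.append(float(row["time_min"]))
        spectra.append(read_spectrum(p))
    return SpectralSeries(np.array(times), tuple(spectra))


def write_series_manifest(series: SpectralSeries, outdir: str,
                          stem: str = "slice") -> str:
    """Write per-time csv files plus ``manifest.csv``; returns manifest path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, (t, s) in enumerate(zip(series.times, series.spectra)):
        fname = f"{stem}_{i:03d}.csv"
        write_spectrum(s, os.path.join(outdir, fname))
        rows.append({"time_min": t, "path": fname})
    manifest_path = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def read_series_wide(path: str) -> SpectralSeries:
    """Read a wide table: first column wavenumber, remaining columns named by
    time in minutes."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise SpectrumParseError(
            f"{path}: wide table needs a wavenumber column plus >= 2 time columns"
        )
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectrumParseError(
            f"{path}: wide-table time columns must be numeric minutes"
        ) from exc
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(wn)
    wn = wn[order]
    spectra = tuple(
        Spectrum(wn, df.iloc[:, j + 1].to_numpy(dtype=float)[order],
                 {"source": os.fspath(path)})
        for j in range(len(times))
    )
    return SpectralSeries(times, spectra)


def write_series_wide(series: SpectralSeries, path: str) -> None:
    data = {"wavenumber_cm1": series.wavenumbers}
    for t, s in zip(series.times, series.spectra):
        data[f"{t:g}"] = s.absorbance
    pd.DataFrame(data).to_csv(path, index=False)
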