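"""Quick-look plots for fits and trajectories (matplotlib, Agg-safe).

Data are stored ascending in wavenumber; spectra are plotted with the
axis reversed, as spectroscopists read them.  Comparison plots
max-normalise within each window — a display choice only, never applied
to the fitted data.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402  (headless environments)
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_fit", "plot_trajectories", "plot_product_kinetics"]


def plot_fit(result, ax=None):
    """Window data, fitted model, per-component profiles, residuals."""
    from .lineshape import eval_voigt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = result.data.wavenumbers
    ax.plot(x, result.data.absorbance, "k.", ms=2, label="data")
    ax.plot(x, result.predict(), "r-", lw=1, label="fit")
    base = result.model.baseline(x, result.model.nu_ref)
    for i, c in enumerate(result.components):
        ax.plot(x, base + eval_voigt(x, c), "--", lw=0.8, label=f"comp {i}")
    ax.plot(x, result.residuals + float(np.min(result.data.absorbance)), "b-",
            lw=0.5, alpha=0.6, label="residual (offset)")
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("absorbance (AU)")
    ax.invert_xaxis()
    ax.legend(fontsize=7)
    return ax


def plot_trajectories(results, band_ids=None, axes=None):
    """Center-vs-time panels for the tracked bands."""
    band_ids = band_ids or (results.config.summary_bands or list(results.trajectories))
    if axes is None:
        _, axes = plt.subplots(1, len(band_ids), figsize=(3 * len(band_ids), 3),
                               squeeze=False)
        axes = axes[0]
    for ax, band_id in zip(axes, band_ids):
        t = results.trajectories[band_id]
        ok = t.converged
        ax.errorbar(t.times[ok], t.centers[ok], yerr=t.center_sds[ok],
                    fmt="o-", ms=3, lw=0.8)
        ax.set_title(band_id, fontsize=9)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("center (cm$^{-1}$)")
    return axes


def plot_product_kinetics(results, band_id=None, ax=None):
    """Product-band area rise with the exponential-plateau fit and t95."""
    band_id = band_id or results.config.product_band
    traj = results.trajectories[band_id]
    fitp = results.plateau(band_id)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ok = traj.converged
    ax.errorbar(traj.times[ok], traj.areas[ok], yerr=traj.area_sds[ok],
                fmt="ko", ms=3)
    if fitp.valid:
        tt = np.linspace(traj.times[0], traj.times[-1], 200)
        ax.plot(tt, fitp.A0 + fitp.Ainf * (1 - np.exp(-fitp.k * (tt - traj.times[0]))),
                "r-", lw=1)
        ax.axvline(traj.times[0] + fitp.t95, ls="--", c="gray",
                   label=f"t95 = {fitp.t95:.1f} min")
        ax.legend(fontsize=8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("fitted area (AU cm$^{-1}$)")
    return ax
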