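"""Series tracking: trajectories, shifts, redistribution, plateau
kinetics, stability and cross-scenario comparison."""

import math

import numpy as np
import pytest

from voigttrack.lineshape import VoigtComponent, eval_voigt
from voigttrack.peakfit import fit_static_references
from voigttrack.spectra import SpectralSeries, Spectrum, Window
from voigttrack.synthetic import Scenario, generate_series
from voigttrack.tracking import (
    PeakTrajectory,
    compare_scenarios,
    compute_shift,
    fit_plateau,
    load_tracking_config,
    redistribution_analysis,
    stability_check,
    track_series,
)


def _small_scenario(shift_b3=-5.0, ctrl_drift=0.0, k=0.5, noise=2e-4):
    """Compact reaction scenario covering the default tracked windows."""
    return Scenario(
        name="mini",
        grid={"lo": 1000.0, "hi": 1560.0, "spacing": 0.5},
        times={"t0": 0.0, "t_end": 21.0, "step": 1.5},
        rate_k=k,
        noise_sd=noise,
        bands=[
            {"band_id": "B1", "center_start": 1510.0, "center_end": 1516.0,
             "area_start": 0.3, "area_end": 0.3},
            {"band_id": "B2", "center_start": 1494.0, "center_end": 1498.0,
             "area_start": 0.3, "area_end": 0.3},
            {"band_id": "B3", "center_start": 1345.0,
             "center_end": 1345.0 + shift_b3, "area_start": 0.28,
             "area_end": 0.2},
            {"band_id": "B4", "center_start": 1294.0, "center_end": 1291.0,
             "area_start": 0.25, "area_end": 0.18},
            {"band_id": "PI1077", "center_start": 1077.0, "center_end": 1077.0,
             "area_start": 0.02, "area_end": 0.42},
            {"band_id": "ALP1045", "center_start": 1045.0, "center_end": 1045.0,
             "area_start": 0.18, "area_end": 0.18},
            {"band_id": "CTRL1460", "center_start": 1460.0,
             "center_end": 1460.0 + ctrl_drift, "area_start": 0.22,
             "area_end": 0.22},
        ],
    )


@pytest.fixture(scope="module")
def static_refs():
    from voigttrack.synthetic import generate_static

    statics = {
        sp: generate_static(sp, seed=100 + i)[0]
        for i, sp in enumerate(("ALP", "PNPP", "PNP", "Pi"))
    }
    return fit_static_references(statics)


class TestTrackSeries:
    def test_constant_centers_give_flat_trajectories(self, static_refs):
        sc = _small_scenario(shift_b3=0.0)
        sc = sc.model_copy(update={"bands": [
            b.model_copy(update={"center_end": b.center_start})
            for b in sc.bands
        ]})
        series, _ = generate_series(sc, seed=1)
        res = track_series(series, static_refs, seed=1)
        for band_id in ("B1", "B2", "B3", "B4", "CTRL1460"):
            traj = res[band_id]
            ok = traj.converged
            drift = np.abs(traj.centers[ok] - traj.centers[ok][0])
            # flat within ~2x the reported per-point uncertainty
            bound = 2.0 * np.maximum(traj.center_sds[ok], 0.02)
            assert np.all(drift <= drift * 0 + np.maximum(bound, 0.15))

    def test_product_band_area_rises_to_plateau(self, static_refs):
        sc = _small_scenario()
        series, _ = generate_series(sc, seed=2)
        res = track_series(series, static_refs, seed=2)
        areas = res["PI1077"].areas
        # monotone after light smoothing at the noise scale
        sm = np.convolve(areas, np.ones(3) / 3, mode="valid")
        assert np.all(np.diff(sm) > -0.01)
        assert areas[-1] > 10 * areas[0]

    def test_slice_order_permutation_invariance(self, static_refs):
        sc = _small_scenario()
        series, _ = generate_series(sc, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(series))
        shuffled = SpectralSeries(
            series.times[perm], tuple(series.spectra[i] for i in perm)
        )
        r1 = track_series(series, static_refs, seed=3)
        r2 = track_series(shuffled, static_refs, seed=3)
        for band_id in r1.trajectories:
            assert np.array_equal(r1[band_id].centers, r2[band_id].centers)
            assert np.array_equal(r1[band_id].areas, r2[band_id].areas)

    def test_unknown_reference_label_raises(self, static_refs):
        cfg = load_tracking_config()
        cfg = cfg.model_copy(deep=True)
        cfg.windows[0].bands[0].ref_label = "nonexistent_band"
        sc = _small_scenario()
        series, _ = generate_series(sc, seed=4)
        with pytest.raises(KeyError, match="nonexistent_band"):
            track_series(series, static_refs, config=cfg)


class TestComputeShift:
    def _traj(self, centers, sds=None, conv=None):
        n = len(centers)
        return PeakTrajectory(
            band_id="X",
            times=1.5 * np.arange(n),
            centers=np.asarray(centers, float),
            center_sds=np.asarray(sds if sds is not None else [0.01] * n),
            areas=np.ones(n), area_sds=np.full(n, 0.01),
            heights=np.ones(n), sigmas=np.full(n, 3.0), gammas=np.full(n, 3.0),
            converged=np.asarray(conv if conv is not None else [True] * n),
        )

    def test_constant_trajectory_zero_shift(self):
        d, sd = compute_shift(self._traj([1500.0] * 10))
        assert d == 0.0
        assert sd == pytest.approx(math.sqrt(2) * 0.01)

    def test_uses_converged_endpoints_only(self):
        traj = self._traj([1500.0, 1501.0, 1502.0, 1509.0],
                          conv=[True, True, True, False])
        d, _ = compute_shift(traj)
        assert d == pytest.approx(2.0)

    def test_too_few_converged_points_error(self):
        traj = self._traj([1500.0, 1501.0], conv=[True, False])
        with pytest.raises(ValueError, match="converged"):
            compute_shift(traj)


class TestPlateau:
    def test_noiseless_closed_form_t95(self):
        k = math.log(20.0) / 4.5
        t = np.arange(0, 33.01, 1.5)
        a = 0.02 + 0.4 * (1 - np.exp(-k * t))
        fit = fit_plateau(t, a)
        assert fit.valid
        assert fit.t95 == pytest.approx(4.5, abs=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)

    def test_constant_series_flagged_no_rise(self):
        t = np.arange(0, 33.01, 1.5)
        a = np.full(t.size, 0.3)
        fit = fit_plateau(t, a, noise_sd=1e-3)
        assert not fit.valid

    def test_rate_recovery_under_noise(self):
        k = 0.5
        rng = np.random.default_rng(21)
        rel_errors = []
        t = np.arange(0, 33.01, 1.5)
        for _ in range(100):
            a = 0.02 + 0.4 * (1 - np.exp(-k * t)) + rng.normal(0, 2e-3, t.size)
            fit = fit_plateau(t, a)
            rel_errors.append(abs(fit.k - k) / k)
        assert np.mean(rel_errors) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_plateau([0, 1, 2], [0.0, 0.1, 0.2])


class TestStability:
    def _traj_centers(self, centers):
        n = len(centers)
        return PeakTrajectory(
            band_id="CTRL", times=1.5 * np.arange(n),
            centers=np.asarray(centers, float), center_sds=np.full(n, 0.01),
            areas=np.ones(n), area_sds=np.full(n, 0.01), heights=np.ones(n),
            sigmas=np.full(n, 3.0), gammas=np.full(n, 3.0),
            converged=np.full(n, True),
        )

    def test_constant_control_passes(self):
        r = stability_check(self._traj_centers([1460.0] * 10), tol=1.0)
        assert r.passed and r.max_excursion == 0.0

    def test_injected_drift_fails(self, static_refs):
        sc = _small_scenario(ctrl_drift=3.0)
        series, _ = generate_series(sc, seed=6)
        res = track_series(series, static_refs, seed=6)
        st = res.stability()
        assert not st.passed
        assert st.max_excursion == pytest.approx(3.0, abs=0.5)


class TestRedistribution:
    def _pair_series(self, k=0.3, noise=2e-4, seed=1):
        grid = 1540.0 + 0.5 * np.arange(280)
        times = np.arange(0, 33.01, 1.5)
        rng = np.random.default_rng(seed)
        spectra = []
        for t in times:
            a_lo = 0.3 * math.exp(-k * t)
            a_hi = 0.3 * (1 - math.exp(-k * t))
            y = eval_voigt(grid, VoigtComponent(max(a_lo, 1e-9), 1606.0, 3.5, 3.0))
            y = y + eval_voigt(grid, VoigtComponent(max(a_hi, 1e-9), 1617.0, 3.5, 3.0))
            if noise:
                y = y + rng.normal(0, noise, grid.size)
            spectra.append(Spectrum(grid, y))
        return SpectralSeries(times, tuple(spectra)), k

    def test_exchange_kinetics_recovered(self):
        series, k = self._pair_series()
        r = redistribution_analysis(series, noise_sd=2e-4)
        f_true = 1 - np.exp(-k * series.times)
        rms = float(np.sqrt(np.mean((r.product_fraction - f_true) ** 2)))
        assert rms < 0.03
        assert r.max_center_motion < 0.5

    def test_centroid_drifts_while_centers_static(self):
        series, _ = self._pair_series()
        r = redistribution_analysis(series, noise_sd=2e-4)
        assert r.centroid_drift >= 5.0
        assert r.max_center_motion < 0.5

    def test_equal_constant_areas_fraction_half(self):
        grid = 1540.0 + 0.5 * np.arange(280)
        times = np.arange(0, 6.01, 1.5)
        y = (eval_voigt(grid, VoigtComponent(0.3, 1606.0, 3.5, 3.0))
             + eval_voigt(grid, VoigtComponent(0.3, 1617.0, 3.5, 3.0)))
        series = SpectralSeries(
            times, tuple(Spectrum(grid, y) for _ in times))
        r = redistribution_analysis(series, noise_sd=1e-6)
        assert np.allclose(r.product_fraction, 0.5, atol=0.01)

    def test_all_intensity_low_component(self):
        grid = 1540.0 + 0.5 * np.arange(280)
        times = np.arange(0, 6.01, 1.5)
        y = eval_voigt(grid, VoigtComponent(0.3, 1606.0, 3.5, 3.0))
        series = SpectralSeries(
            times, tuple(Spectrum(grid, y) for _ in times))
        r = redistribution_analysis(series, noise_sd=1e-6)
        assert np.allclose(r.product_fraction, 0.0, atol=0.02)
        assert np.allclose(r.apparent_centroid, 1606.0, atol=1.0)


class TestCompareScenarios:
    def test_duplicate_scenario_zero_spread(self, static_refs):
        sc = _small_scenario()
        series, _ = generate_series(sc, seed=7)
        res = track_series(series, static_refs, seed=7)
        summary = compare_scenarios({"a": res, "b": res})
        assert np.allclose(summary.t0_spread["t0_spread_cm1"], 0.0)

    def test_shift_ordering_across_loadings(self, static_refs):
        results = {}
        for name, b3 in (("strong", -5.0), ("weak", -1.0)):
            series, _ = generate_series(_small_scenario(shift_b3=b3), seed=8)
            results[name] = track_series(series, static_refs, seed=8)
        summary = compare_scenarios(results)
        t = summary.table.set_index(["band_id", "scenario"])
        assert abs(t.loc[("B3", "strong"), "delta_cm1"]) > abs(
            t.loc[("B3", "weak"), "delta_cm1"])
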