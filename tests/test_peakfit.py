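"""Bounded windowed fitting: parameter recovery, bounds enforcement,
model selection and static-reference fitting."""

import numpy as np
import pytest

from voigttrack.lineshape import VoigtComponent, apex_height
from voigttrack.peakfit import (
    FitConstraints,
    VoigtWindowModel,
    WindowModel,
    assign_components,
    fit_static_references,
    fit_window,
    load_reference_table,
    select_components,
    select_family,
)
from voigttrack.preprocess import detect_peaks
from voigttrack.spectra import Spectrum, Window

from conftest import make_band_spectrum


class TestFitWindow:
    def test_noiseless_single_voigt_recovered(self, single_voigt_spectrum):
        s, truth = single_voigt_spectrum
        w = Window(1000.0, 1150.0)
        init = VoigtComponent(0.5, 1075.0, 3.0, 3.0)
        res = fit_window(s, WindowModel(w, "voigt", (init,)),
                         FitConstraints(center_tol=7.5),
                         center_refs=[1077.0], noise_sd=1e-6)
        assert res.converged
        c = res.components[0]
        assert c.center == pytest.approx(truth.center, abs=1e-4)
        assert c.area == pytest.approx(truth.area, rel=1e-5)
        assert c.sigma == pytest.approx(truth.sigma, rel=1e-4)
        assert c.gamma == pytest.approx(truth.gamma, rel=1e-4)
        # baseline recovered jointly: predictions match data everywhere
        assert np.max(np.abs(res.predict() - res.data.absorbance)) < 1e-8

    def test_all_zero_spectrum_gives_zero_area(self):
        g = 1000.0 + 0.5 * np.arange(301)
        s = Spectrum(g, np.zeros(301))
        res = fit_window(
            s,
            WindowModel(Window(1000.0, 1150.0), "voigt",
                        (VoigtComponent(0.1, 1077.0, 3.0, 3.0),)),
            noise_sd=1e-9,
        )
        assert res.components[0].area == pytest.approx(0.0, abs=1e-6)
        assert abs(res.params["b_intercept"]) < 1e-6

    def test_initial_center_outside_window_rejected(self):
        g = 1000.0 + 0.5 * np.arange(301)
        s = Spectrum(g, np.zeros(301))
        with pytest.raises(ValueError, match="outside window"):
            fit_window(
                s,
                WindowModel(Window(1000.0, 1050.0), "voigt",
                            (VoigtComponent(0.1, 1077.0, 3.0, 3.0),)),
            )

    def test_bounds_respected_exactly(self):
        # data pushes the center beyond its allowed box; the optimiser
        # must stop at the bound, not clip afterwards
        g = 1000.0 + 0.5 * np.arange(301)
        s = make_band_spectrum([VoigtComponent(1.0, 1090.0, 4.0, 6.0)], g,
                               noise_sd=2e-4, seed=5)
        res = fit_window(
            s,
            WindowModel(Window(1000.0, 1150.0), "voigt",
                        (VoigtComponent(0.5, 1077.0, 3.0, 3.0),)),
            FitConstraints(center_tol=7.5),
            center_refs=[1077.0],
            noise_sd=2e-4,
        )
        c = res.components[0]
        assert 1077.0 - 7.5 <= c.center <= 1077.0 + 7.5
        assert 1.0 <= c.sigma <= 15.0
        assert 1.0 <= c.gamma <= 20.0
        assert c.area >= 0.0
        assert c.center == pytest.approx(1077.0 + 7.5, abs=1e-6)

    def test_two_component_monte_carlo_recovery(self):
        g = 1550.0 + 0.5 * np.arange(241)
        comps = [VoigtComponent(0.3, 1606.0, 3.5, 2.0),
                 VoigtComponent(0.3, 1617.0, 3.5, 2.0)]
        w = Window(1575.0, 1650.0)
        good = 0
        n = 30
        for seed in range(n):
            s = make_band_spectrum(comps, g, noise_sd=2e-4, seed=seed)
            res = fit_window(
                s,
                WindowModel(w, "voigt",
                            (VoigtComponent(0.2, 1606.0, 3.0, 3.0),
                             VoigtComponent(0.2, 1617.0, 3.0, 3.0))),
                FitConstraints(center_tol=7.5),
                noise_sd=2e-4,
                seed=seed,
            )
            e1 = abs(res.components[0].center - 1606.0)
            e2 = abs(res.components[1].center - 1617.0)
            if res.converged and max(e1, e2) < 0.3:
                good += 1
        assert good >= int(0.9 * n)  # spec rate is 95/100; small-n slack

    def test_grid_shift_equivariance(self):
        g = 1000.0 + 0.5 * np.arange(301)
        s = make_band_spectrum([VoigtComponent(1.0, 1077.0, 4.0, 6.0)], g,
                               noise_sd=1e-4, seed=9)
        shift = 250.0
        s2 = Spectrum(g + shift, s.absorbance)
        kw = dict(fc=FitConstraints(center_tol=7.5), noise_sd=1e-4)
        r1 = fit_window(s, WindowModel(Window(1000, 1150), "voigt",
                                       (VoigtComponent(0.5, 1077.0, 3.0, 3.0),)),
                        **kw)
        r2 = fit_window(s2, WindowModel(Window(1000 + shift, 1150 + shift), "voigt",
                                        (VoigtComponent(0.5, 1077.0 + shift, 3.0, 3.0),)),
                        **kw)
        assert r2.components[0].center - r1.components[0].center == pytest.approx(
            shift, abs=1e-6)
        assert r2.components[0].area == pytest.approx(r1.components[0].area,
                                                      rel=1e-6)
        assert r2.components[0].sigma == pytest.approx(r1.components[0].sigma,
                                                       rel=1e-6)

    def test_noiseless_fit_from_detection_initialisation(self):
        g = 1000.0 + 0.5 * np.arange(301)
        truth = VoigtComponent(1.0, 1077.0, 4.0, 6.0)
        s = make_band_spectrum([truth], g, baseline=(0.01, 1e-5))
        w = Window(1030.0, 1130.0)
        guesses = detect_peaks(s, w, min_prominence=1e-3)
        assert len(guesses) >= 1
        h0 = apex_height(VoigtComponent(1.0, 0.0, 3.0, 3.0))
        comps = tuple(VoigtComponent(x.height / h0, x.center, 3.0, 3.0)
                      for x in guesses[:1])
        res = fit_window(s, WindowModel(w, "voigt", comps),
                         FitConstraints(center_tol=7.5), noise_sd=1e-9)
        n = len(res.residuals)
        assert res.rss < (1e-8 * apex_height(truth)) ** 2 * n

    def test_single_voigt_center_recovery_ensemble(self):
        # random widths and SNR; bias < 0.05 cm^-1, 95th pct error < 0.5
        rng = np.random.default_rng(77)
        errors = []
        n = 200
        for i in range(n):
            sigma = rng.uniform(1.0, 15.0)
            gamma = rng.uniform(1.0, 20.0)
            snr = rng.uniform(30.0, 300.0)
            noise = 2e-4
            center = 1200.0 + rng.uniform(-5.0, 5.0)
            height = snr * noise
            area = height / apex_height(VoigtComponent(1.0, 0.0, sigma, gamma))
            g = 1050.0 + 0.5 * np.arange(601)  # 1050-1350
            s = make_band_spectrum([VoigtComponent(area, center, sigma, gamma)],
                                   g, noise_sd=noise,
                                   seed=int(rng.integers(2**31)))
            res = fit_window(
                s,
                WindowModel(Window(1100.0, 1300.0), "voigt",
                            (VoigtComponent(area, 1200.0, 3.0, 3.0),)),
                FitConstraints(center_tol=7.5),
                center_refs=[1200.0],
                noise_sd=noise,
                seed=i,
            )
            errors.append(res.components[0].center - center)
        errors = np.array(errors)
        assert abs(np.mean(errors)) < 0.05
        assert np.quantile(np.abs(errors), 0.95) < 0.5


class TestSelectFamily:
    def test_noiseless_gaussian_prefers_gaussian(self):
        g = 1000.0 + 0.5 * np.arange(301)
        s = make_band_spectrum([VoigtComponent(1.0, 1077.0, 4.0, 0.0)], g)
        fam = select_family(s, Window(1030.0, 1130.0), noise_sd=1e-9)
        assert fam == "gaussian"

    @pytest.mark.parametrize(
        "truth_widths,expected,min_rate",
        [((4.0, 0.0), "gaussian", 0.9), ((4.0, 4.0), "voigt", 0.9)],
    )
    def test_family_recovery_rate(self, truth_widths, expected, min_rate):
        sigma, gamma = truth_widths
        g = 1000.0 + 0.5 * np.arange(301)
        noise = 2e-4
        comp_kwargs = dict(center=1077.0)
        truth = VoigtComponent(
            100 * noise / apex_height(VoigtComponent(1.0, 0.0, max(sigma, 1e-6),
                                                     gamma)),
            1077.0, sigma, gamma)  # SNR 100
        hits = 0
        n = 40
        for seed in range(n):
            s = make_band_spectrum([truth], g, noise_sd=noise, seed=1000 + seed)
            fam = select_family(s, Window(1030.0, 1130.0), noise_sd=noise,
                                seed=seed)
            hits += fam == expected
        assert hits >= int(min_rate * n)


class TestSelectComponents:
    def test_single_band_keeps_k1(self):
        g = 1000.0 + 0.5 * np.arange(301)
        noise = 1e-4
        truth = VoigtComponent(0.5, 1077.0, 3.5, 3.0)
        s = make_band_spectrum([truth], g, noise_sd=noise, seed=3)
        res = select_components(s, Window(1030.0, 1130.0), noise_sd=noise)
        assert len(res.components) == 1

    def test_overlapped_pair_needs_k2(self):
        g = 1550.0 + 0.5 * np.arange(241)
        noise = 1e-4
        comps = [VoigtComponent(0.3, 1606.0, 3.5, 2.0),
                 VoigtComponent(0.3, 1617.0, 3.5, 2.0)]
        s = make_band_spectrum(comps, g, noise_sd=noise, seed=4)
        res = select_components(s, Window(1575.0, 1650.0), noise_sd=noise)
        assert len(res.components) == 2
        centers = sorted(c.center for c in res.components)
        assert abs(centers[0] - 1606.0) < 1.0
        assert abs(centers[1] - 1617.0) < 1.0

    def test_three_bands_capped_at_three(self):
        g = 1520.0 + 0.5 * np.arange(301)
        noise = 1e-4
        comps = [VoigtComponent(0.3, 1583.0, 3.5, 2.0),
                 VoigtComponent(0.3, 1595.0, 3.5, 2.0),
                 VoigtComponent(0.3, 1606.0, 3.5, 2.0)]
        s = make_band_spectrum(comps, g, noise_sd=noise, seed=5)
        res = select_components(s, Window(1555.0, 1640.0), noise_sd=noise)
        assert len(res.components) == 3


class TestStaticReferences:
    def test_alp_reference_centers_recovered(self):
        from voigttrack.synthetic import generate_static

        s, truth = generate_static("ALP", seed=11)
        refs = fit_static_references({"ALP": s})
        refs = refs[refs["species"] == "ALP"]
        table = load_reference_table()
        table_alp = table[(table["species"] == "ALP")
                          & (table["role"] == "primary")]
        assert len(table_alp) == 11
        for _, row in table_alp.iterrows():
            fitted = refs[refs["label"] == row["label"]].iloc[0]
            assert not fitted["missing"]
            assert fitted["fitted_center_cm1"] == pytest.approx(
                row["literature_center_cm1"], abs=0.5)

    def test_pi_marker_band(self):
        from voigttrack.synthetic import generate_static

        s, _ = generate_static("Pi", seed=12)
        refs = fit_static_references({"Pi": s})
        row = refs[refs["label"] == "pi_1077"].iloc[0]
        assert row["fitted_center_cm1"] == pytest.approx(1077.0, abs=0.2)

    def test_empty_spectrum_all_missing(self):
        g = 400.0 + 0.5 * np.arange(7201)
        s = Spectrum(g, np.random.default_rng(0).normal(0, 1e-4, g.size))
        refs = fit_static_references({"Pi": s})
        assert refs["missing"].all()

    def test_species_absent_from_inputs_skipped(self):
        from voigttrack.synthetic import generate_static

        s, _ = generate_static("Pi", seed=12)
        refs = fit_static_references({"Pi": s})
        assert set(refs["species"]) == {"Pi"}


class TestAssignment:
    def test_nearest_assignment_prevents_label_switch(self):
        assert assign_components([1617.2, 1605.8], [1606.0, 1617.0]) == [1, 0]

    def test_identity_when_ordered(self):
        assert assign_components([1606.1, 1616.9], [1606.0, 1617.0]) == [0, 1]


def test_summary_contains_estimates(single_voigt_spectrum):
    s, truth = single_voigt_spectrum
    model = VoigtWindowModel(
        s, Window(1000.0, 1150.0),
        (VoigtComponent(0.5, 1075.0, 3.0, 3.0),),
        constraints=FitConstraints(center_tol=7.5),
        center_refs=[1077.0],
        noise_sd=1e-6,
    )
    res = model.fit()
    text = res.summary()
    assert "1077.000" in text
    assert "voigt" in text
    assert "bic" in text.lower()
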