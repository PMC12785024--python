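# voigttrack

Static-reference-anchored Voigt deconvolution and band tracking for
time-resolved ATR-FTIR monitoring of enzymatic catalysis.

## The problem

Attenuated-total-reflection FTIR can watch an enzymatic reaction in
aqueous solution in real time: as alkaline phosphatase (ALP) hydrolyses
p-nitrophenyl phosphate (PNPP) into p-nitrophenol (PNP) and inorganic
phosphate (Pi), substrate bands fade, product bands grow, and several
nitro/aromatic and fingerprint modes shift by a few cm⁻¹.  Extracting
those shifts reliably is hard because solution-phase IR bands overlap,
drift on a sloping baseline, and sit close to the noise floor.

`voigttrack` implements the analysis side of that experiment for
spectroscopists who have a stack of absorbance spectra and need
defensible peak trajectories:

1. **Windowed Voigt deconvolution.** Each predefined spectral window is
   fitted with ≤3 Voigt profiles V(ν; A, ν₀, σ, γ) plus a linear
   baseline by bounded nonlinear least squares — non-negative areas,
   widths σ ∈ [1, 15] cm⁻¹ and γ ∈ [1, 20] cm⁻¹, centers boxed around
   reference values.  The Voigt profile is evaluated exactly through the
   Faddeeva function, V(ν) = A·Re[w(z)]/(σ√2π) with
   z = (ν − ν₀ + iγ)/(σ√2).
2. **Static anchoring.** Band centers are first fitted freely (±25 cm⁻¹)
   in static reference spectra of the pure species; those fitted
   positions then constrain the corresponding bands in every time slice
   (±5–10 cm⁻¹), which kills label switching and drift artifacts.
3. **Per-slice independent tracking.** Every time slice is fitted on its
   own; trajectories, net shifts Δν = ν(t_last) − ν(t_first) with
   propagated 1σ, an intensity-redistribution analysis for overlapping
   band pairs, and exponential-plateau kinetics
   A(t) = A₀ + A_inf·(1 − e^(−kt)) with completion time t95 = ln(20)/k
   for the product phosphate band.
4. **Model checking.** Savitzky–Golay derivative peak detection for
   initialisation, AIC/BIC comparison of Gaussian/Lorentzian/Voigt
   families, residual-driven component-count selection, and a
   drift-control band that must stay put.

Because the underlying raw measurements of this kind of experiment are
rarely archived, the package ships a first-class synthetic generator
(`voigttrack.synthetic`) that produces reaction series with exact ground
truth — multi-band Voigt spectra on 400–4000 cm⁻¹ grids, 1.5 min time
resolution over 0–33 min, first-order conversion kinetics, white noise
and per-slice baseline drift — including three packaged
enzyme-loading scenarios whose band trajectories encode the reported
concentration series (high: +8, +5, −5, −4 cm⁻¹; mid: +0.80, +0.30,
−1.7, −3.8 cm⁻¹; low: ≈0 … −1 cm⁻¹; product rise with t95 = 4.5 min).

## Worked example

```python
from voigttrack import synthetic, peakfit, tracking

# simulate the high-loading reaction and the four static references
sc = synthetic.load_packaged_scenario("high_alp")
series, truth = synthetic.generate_series(sc, seed=0)
statics = {sp: synthetic.generate_static(sp, seed=i)[0]
           for i, sp in enumerate(("ALP", "PNPP", "PNP", "Pi"))}

# anchor: fit reference band centers, then track every slice
refs = peakfit.fit_static_references(statics)
res = tracking.track_series(series, refs, seed=0)
print(res.summary())
```

prints

```
Series tracking summary
================================================================
        B1:  1509.991 ->  1517.997 cm-1   delta =  +8.007 +/- 0.043 cm-1
        B2:  1494.099 ->  1499.015 cm-1   delta =  +4.916 +/- 0.035 cm-1
        B3:  1344.960 ->  1340.035 cm-1   delta =  -4.925 +/- 0.040 cm-1
        B4:  1293.991 ->  1289.965 cm-1   delta =  -4.026 +/- 0.043 cm-1
product band PI1077: k = 0.6752 min-1, t95 = 4.44 min
drift control CTRL1460: PASS (max excursion 0.127 cm-1, tol 1.00)
```

Reading the output: the two nitro/aromatic bands blue-shift by +8 and
+5 cm⁻¹ and the two substrate-side fingerprint bands red-shift by −5 and
−4 cm⁻¹, each quoted with the propagated 1σ of the endpoint fits; the
1077 cm⁻¹ phosphate band rises with rate k so that the reaction is 95%
complete at t95 ≈ 4.4 min; and the CH₂-scissoring control band moved
less than 0.13 cm⁻¹ over the whole run, so the shifts are not an
instrument/thickness artifact.  The ground truth behind this simulation
(`truth["bands"]["B1"]["delta_nu"]` = +8.000) confirms the pipeline
recovers the encoded shifts to well under the instrument resolution.

The same workflow is available from the shell:

```sh
voigttrack simulate high_alp --seed 0 --outdir runs/high
voigttrack fit-static runs/high/statics --outdir runs/high_refs
voigttrack track --manifest runs/high/manifest.csv \
    --refs runs/high_refs/fitted_references.csv --outdir runs/high_tracked
voigttrack compare runs/high_tracked runs/mid_tracked --out shifts.csv
```

Single-window fitting follows the familiar model/results idiom:

```python
from voigttrack import VoigtWindowModel, VoigtComponent, Window

model = VoigtWindowModel(spectrum, Window(1030, 1130),
                         [VoigtComponent(0.3, 1077.0, 3.0, 3.0)])
result = model.fit()
print(result.summary())          # estimates, 1-sigma, AIC/BIC, residual RMS
```

## Layout

- `voigttrack.spectra` — `Spectrum` / `SpectralSeries` containers, csv +
  minimal JCAMP-DX I/O, resampling, blank subtraction, windowing
- `voigttrack.preprocess` — Savitzky–Golay smoothing/derivatives, peak
  candidates, robust noise estimation
- `voigttrack.lineshape` — exact Voigt/Gaussian/Lorentzian evaluation,
  FWHM, AIC/BIC
- `voigttrack.peakfit` — `VoigtWindowModel` → `VoigtFitResult`, family and
  component-count selection, static reference fitting
- `voigttrack.tracking` — `SeriesTracker` → `TrackingResults`,
  trajectories, shifts, redistribution, plateau kinetics, stability
- `voigttrack.synthetic` — scenario schema, generators, packaged scenarios
- `voigttrack.cli` — `voigttrack simulate | fit-static | track | compare`

See `docs/methods.md` for the modelling assumptions, default parameter
choices and known limitations.
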