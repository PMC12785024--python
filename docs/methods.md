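# Methods

This note documents the models behind `voigttrack`, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Line-shape model

Solution-phase IR bands combine homogeneous (lifetime, collisional) and
inhomogeneous (environmental-distribution) broadening, so each band is a
Voigt profile — the convolution of a Gaussian of width σ and a
Lorentzian of half-width-at-half-maximum γ.  Evaluation uses the
Faddeeva function w(z):

    V(ν) = A · Re[w(z)] / (σ√(2π)),   z = (ν − ν₀ + iγ) / (σ√2)

with the closed-form Lorentzian as the σ = 0 limit.  γ denotes the
Lorentzian **HWHM** (the common "Lorentzian γ" convention); the
Lorentzian FWHM is 2γ.  Components are parameterised by integrated
**area** A (AU·cm⁻¹), not apex height: area is the physically additive
quantity and decorrelates from the widths during fitting.  Apex height
and the Olivero–Longbothum FWHM

    f ≈ 0.5346·f_L + √(0.2166·f_L² + f_G²),  f_L = 2γ, f_G = 2σ√(2 ln 2)

are derived quantities (the FWHM approximation is good to ~0.02% across
all mixing ratios; the test suite verifies it against half-maximum
root-finding).  Note that the Voigt far tail is Lorentzian, so the mass
outside ±L is ≈ 2Aγ/(πL); truncated numerical integrals of a
Lorentzian-dominated profile recover A only after accounting for that
tail.

## Windowed fitting

A window model is 1–3 Voigt components **plus a linear baseline**, fitted
jointly by bounded trust-region least squares (`scipy.optimize.least_squares`,
TRF).  The baseline is referenced to the window midpoint for
conditioning and is always free and unbounded — it is part of the model,
never pre-subtracted.  Bounds, enforced by the optimiser (no post-hoc
clipping):

| parameter | bound | rationale |
|---|---|---|
| area | ≥ 0 | absorbance bands are non-negative |
| center | reference ± tol | static anchoring (below) |
| σ | 1–15 cm⁻¹ | physically reasonable Gaussian widths |
| γ | 1–20 cm⁻¹ | physically reasonable Lorentzian widths |

Optimiser tolerances are 1e-10 (cost, step and gradient) with at most
400 evaluations per start; these are cheap problems and the tight
tolerances favour bit-reproducibility.  On non-convergence up to three
restarts are tried with centers jittered by ±tol/2 using deterministic
sub-seeds, after which the result is flagged unconverged.  Parameter
uncertainties are 1σ values from the local linearisation at the
optimum, cov = s²(JᵀJ)⁻¹ with s² = RSS/(n − k).

**Static anchoring.** Reference spectra of the pure species (enzyme,
substrate, product, phosphate) are fitted with centers free within ±25
cm⁻¹ of literature values (the middle of the conventional ±20–30 range);
each band's fitted position then becomes the tracking constraint with a
tight tolerance, default ±7.5 cm⁻¹ (the middle of the ±5–10 convention).
Both tolerances are per-band columns in the packaged reference table;
the strongly shifting nitro band at ~1508 cm⁻¹ uses ±10 so its full
excursion stays inside the constraint box.  A band whose smoothed signal
never rises 5× above the noise within its search range is reported
missing rather than fitted.  Component identity across refits is kept by
nearest-reference Hungarian assignment.

**Family selection.** Gaussian, Lorentzian and Voigt fits are run from a
common initialisation and compared by BIC in the Gaussian-likelihood
least-squares form, BIC = n·ln(RSS/n) + k·ln n (AIC analogously with
2k).  Ties (ΔBIC < 2) go to the family with fewer free width parameters,
then to Gaussian — so on noiseless Gaussian data the extra Voigt
parameter can never win.

**Component count.** Start from the number of detected peak candidates
(1–3).  A (k+1)-th component is accepted only if the k-component fit
leaves residual RMS > 3× the noise SD **and** the extra component
improves BIC by at least 10.  The count is hard-capped at 3 per window;
wider structures belong in separate windows.

## Initialisation and detection

Initial guesses come from lightly smoothed spectra (Savitzky–Golay,
2nd order; odd windows of 5, 7 or 9 points, default 7 — the symmetric
filter requires odd lengths) and are used **only** for initialisation.
Candidates are the union of two channels:

- prominent local maxima of the smoothed signal (prominence ≥ 5σ̂, with
  σ̂ the robust noise estimate 1.4826·MAD(first differences)/√2 from a
  quiet window, default 1900–2250 cm⁻¹);
- negative-curvature minima of the 2nd Savitzky–Golay derivative, which
  resolve shoulders of overlapped bands.  Differentiation amplifies and
  correlates noise, so this channel has its own floor at 5× the robust
  noise level of the derivative trace, requires genuinely negative
  curvature (a saddle between two bands is a local max of −A'' with
  A'' > 0 and is rejected), and every curvature candidate must also
  carry ≥ the prominence floor of signal above the window's edge line —
  curvature locates, amplitude validates.

Candidates closer than the merge tolerance (default 4 cm⁻¹, the nominal
instrument resolution — peaks closer than resolution are not
independently detectable) are merged keeping the larger prominence;
exact ties keep the lower wavenumber.  All thresholds are exposed under
`detection:` in the tracking configuration.

## Tracking, shifts, kinetics

Each time slice of a reaction series is fitted **independently**; the
only shared information is the constraint set from the static
references.  This makes the analysis invariant to slice order (verified
by a permutation test) and keeps per-slice uncertainties honest.  Net
shifts are endpoint differences, Δν = ν(t_last) − ν(t_first) over
converged endpoints, with 1σ propagated from the two endpoint fits —
matching how concentration-series shifts are conventionally quoted.  An
alternative (asymptote of a fitted trajectory model) would be less
noisy but assumes the relaxation form; endpoints do not.

The product readout is the fitted **area** of the comparatively isolated
1077 cm⁻¹ phosphate band, fitted jointly with the neighbouring ~1045
cm⁻¹ protein band; the ~990 cm⁻¹ region is deliberately not used because
it overlaps the ~925 cm⁻¹ protein band and the broad ~847 cm⁻¹ phosphate
tail (the generator includes all three interferers so this choice is
testable).  Completion is operationalised as t95 = ln(20)/k of the
exponential-plateau fit A(t) = A₀ + A_inf(1 − e^(−kt)) — 95% of plateau
is conventional and makes the completion time a closed-form function of
the rate.  A series whose fitted rise is insignificant (A_inf ≤ 2× the
amplitude noise) or whose rate pins at its floor gets a "no-rise" flag
instead of a kinetic claim.

**Redistribution analysis.** The apparent drift of a composite band can
be pure amplitude exchange between two overlapping components with fixed
centers.  The analysis fits two Voigts with centers constrained ±2 cm⁻¹
(tight enough to exclude genuine drift, loose enough for fit
flexibility), areas and widths free per slice, and reports the product
fraction f(t) = A_hi/(A_lo + A_hi) alongside the apparent single-peak
centroid, which drifts by many cm⁻¹ while the component centers stay
put.  The stationarity statistic counts only slices where a component's
center is actually determined: detectable amplitude (area > 5σ_A) and
center uncertainty ≤ tol/4 — the center of a vanishing component is
undefined and wanders inside its constraint box.  The default standalone
window is 1575–1650 cm⁻¹; windows much narrower than ~6× the band FWHM
truncate the Lorentzian tails and bias areas.

**Stability control.** Every tracking run reports a drift-control band
(default the CH₂-scissoring band near 1460 cm⁻¹, present in enzyme and
product and thickness-sensitive): maximum center excursion ≤ 1 cm⁻¹
passes.  A failure flags thickness/carrier artifacts masquerading as
chemical shifts.

## Synthetic data

The generator emulates the statistical structure of kinetic ATR-FTIR
acquisitions with exact ground truth:

- grids 400–4000 cm⁻¹ at 0.25 cm⁻¹ (static) or 0.5 cm⁻¹ (kinetic)
  spacing; kinetic series at 1.5 min resolution over 0–33 min (23
  slices);
- band centers and areas follow an exponential approach sharing the
  conversion rate k, ν(t) = ν_end − (ν_end − ν_start)e^(−kt) — the
  simplest form consistent with smooth saturation synchronised with the
  product rise; a rising band with A_start = A₀, A_end = A₀ + A_inf is
  exactly the plateau model above;
- additive i.i.d. Gaussian noise, default SD 2×10⁻⁴ AU (1×10⁻⁴ for
  static spectra, which average more scans), and per-slice linear
  baseline drift with slope drawn uniformly within ±10⁻⁶ AU/cm⁻¹ —
  plausible DTGS/ATR magnitudes, both configurable, neither a claim
  about any particular instrument;
- sharp bands default to σ = 3.5, γ = 3 cm⁻¹ (FWHM ≈ 12 cm⁻¹, inside the
  fit bounds); broad X–H envelopes (σ ≈ 110 cm⁻¹) are present as
  realistic background only and are never fitting targets.

Three packaged scenarios encode the reported enzyme-concentration
series as ground truth: high loading (10 µM enzyme, 61 mM substrate;
shifts +8, +5, −5, −4 cm⁻¹; product rise k = ln(20)/4.5 min⁻¹), mid
(10 µM, 305 mM; +0.80, +0.30, −1.7, −3.8 cm⁻¹) and low (1 µM, 305 mM;
0, +0.18, 0, −1 cm⁻¹), plus the 1606/1617 cm⁻¹ redistribution pair, the
1583/1595 cm⁻¹ late doublet, the 1460 cm⁻¹ control and the 925/1045/847
cm⁻¹ interferers.  The mid-scenario 1510-band is seeded at
1509.742 → 1510.542 cm⁻¹ so that its net shift is exactly the reported
+0.80 cm⁻¹ while all starting positions stay within 1 cm⁻¹ across
loadings.  Conversion rates for the mid and low scenarios are not
reported; the package uses k = ln(20)/12 ≈ 0.25 min⁻¹ and 0.15 min⁻¹
respectively — slower apparent kinetics at lower enzyme loading, deep
enough that the 33 min endpoint sits within 1% of the asymptotic shift.

**What the generator does not emulate:** ATR penetration-depth
wavelength dependence, water-vapour rotational fine structure,
detector nonlinearity, correlated (1/f) noise, and evaporation-driven
path-length changes.  Passing the recovery tests therefore demonstrates
that the estimator chain is unbiased and well-calibrated under the
stated noise model — not that real spectra meet that model.  The
drift-control band and residual review are the run-time guards for the
differences.

## Numerical and edge-case conventions

- Wavenumber grids are stored strictly ascending; files in descending
  order are sorted on read, duplicated axis values are an error.
- Negative absorbance after blank subtraction is preserved.
- Windows must contain ≥ 8 grid points; below 2 points per free
  parameter ×2 the fit warns.
- An all-zero window converges with zero areas at the bound.
- JCAMP-DX support is the AFFN `(X++(Y..Y))` subset only; compressed
  ordinate dialects raise an explicit unsupported-dialect error rather
  than risking silent corruption.
- Exact prominence ties during candidate merging keep the lower
  wavenumber (determinism).
- All Monte Carlo elements (noise, drift, restart jitter) flow from a
  single user-supplied seed through deterministic sub-seeds.

## Problem sizes in the test suite

The suite exercises the statistical claims at sizes chosen to give
stable pass/fail behaviour at interactive runtimes: the full
three-scenario pipeline runs once per session at seed 0; family
recovery uses 100 simulated windows; single-band center recovery uses
200 random problems; the detection recall/false-positive ensemble uses
60 two-band scenarios; the generator noise check uses 200 seeds on a
compact grid.  The t=0 consistency check compares the measured spread
against 1 cm⁻¹ plus twice its propagated uncertainty, because the
encoded truth places one band pair exactly at the 1 cm⁻¹ boundary and a
point estimate of a boundary quantity exceeds it with probability ~1/2.

## Known limitations

- No global (all-window, all-slice) fitting or multivariate
  decomposition; each window and slice is independent by design.
- Unweighted least squares: heteroscedastic noise (e.g. near strong
  water bands) is not down-weighted.
- Asymmetric line shapes (Fano, skewed) are out of scope.
- Enzymological rate constants are not extracted; the plateau rate is a
  descriptive reaction-progress parameter, not a Michaelis–Menten
  analysis.
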