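# Methods

`fpquant` implements the quantitative workflow used to characterize and rank
green fluorescent proteins (FPs) — StayGold-family variants against the common
references EGFP, mEGFP, mClover3, mNeonGreen and mGreenLantern — across five
measurement families: intrinsic photophysics, photostability, cellular
brightness and maturation, monomericity/dispersibility, and image dynamics.
Every stage can be exercised on synthetic data with known ground truth.

## Photophysical bookkeeping (`spectra`)

Molecular brightness is (ε(λab)/10³) × QY_f in units of 10³ M⁻¹cm⁻¹, with ε
the molar extinction coefficient at the absorbance maximum and QY_f the
fluorescence quantum yield. Printed-table integers use round-half-away-from-
zero. Extinction coefficients follow the alkali-denaturation method: the
denatured GFP-type chromophore absorbs maximally at 447 nm with
ε = 44,000 M⁻¹cm⁻¹, so ε_native = 44,000·A_native(λab)/A_denatured(447) at
equal concentration and path length. ε at any other wavelength is ε_peak
times the max-normalized absorption spectrum, linearly interpolated.

Throughput puts FPs with shifted spectra on equal footing behind one filter
set. Excitation efficiency is the unweighted mean of the max-normalized
excitation spectrum over the excitation band (no lamp-spectrum weighting);
emission detection efficiency is the trapezoid-rule band integral of the
emission spectrum divided by its total integral; channel throughput is their
product. Conventions the measurement itself does not fix and that we chose
once: spectra are resampled to a 1-nm grid by linear interpolation before
any band operation; bands are closed intervals [lo, hi]; dichroics are
ignored beyond what the stated bandpasses imply.

## Irradiance calibration (`beam`)

Wide-field and scanned-field irradiance is measured power divided by the
illuminated/scanned area, I = P/A (W cm⁻²). A Gaussian laser spot of
standard deviation σ has center irradiance I₀ = P/(2πσ²); the relative
intensity at radius r is exp(−r²/(2σ²)). `fov_uniformity` reports the
falloff at the midpoint of the field-of-view edge ("side end" = half the
longer side — this reading reproduces the quoted <11% bound at σ = 28.5 µm
over a 27.1 × 27.1 µm field, computed 10.7%) and, for transparency, at the
corner (20.2%). Interfaces take µm and convert internally to cm.
`photon_flux` converts W cm⁻² to photons cm⁻² s⁻¹ via Φ = I·λ/(hc), with hc
from CODATA constants.

## Photon-budget normalization of photobleaching (`photobleach`)

Raw bleach traces are rescaled so that photostabilities can be compared per
photon emitted rather than per second of wall time:

1. σ_abs = ln(10)·10³·ε/N_A (cm²), with ε taken at the excitation reference
   wavelength (483 nm, the center of the 470–495 nm excitation band). Using
   the single-wavelength ε(483) rather than a band-weighted average is the
   default; the per-FP 483-nm extinction column exists precisely for this.
2. R₀ = QY·σ_abs·Φ(I, λ_ex), the initial emission rate in photons s⁻¹
   molecule⁻¹.
3. emission_rate = 1000·I(t)/I(0); norm_time = t·(R₀/1000).

t₁/₂ is the first crossing of 500 photons s⁻¹ molecule⁻¹ with linear
interpolation between bracketing samples; non-monotone noise is handled by
the first-crossing rule, and traces that never reach 500 are right-censored
at their last time point. Replicates are summarized as mean ± sample SD
(n−1); a single replicate reports SD 0 with an explicit flag.

Two identities define the method and are enforced by tests: any positive
rescaling of raw intensities changes no t₁/₂ (gain invariance), and doubling
the irradiance exactly doubles the time-axis scale factor (irradiance
linearity).

Noisy traces: the first-crossing estimator is biased early on noisy data
(a first-passage effect) and inherits the noise of the t = 0 sample through
the 1000-normalization. `normalize_trace` therefore offers an optional
centered moving average (odd width, recorded in the output); the recovery
analyses use width 5 with 1% additive noise — at that setting the median
relative t₁/₂ error over replicate seeds is ≈1.3%, and the estimator remains
exact for noiseless input. Dark-offset subtraction is available but off by
default. Time zero is first exposure; cumulative exposure equals wall time
(continuous illumination).

## Cellular brightness and maturation (`brightness`)

Each test FP is co-translated with mCherry from a single bicistronic
message, so the green/red ratio cancels expression level. Signal pixels are
those exceeding the mean + 5 SD of pre-expression reference images (5σ
Gaussian false-positive rate < 1e-4; a zero-variance reference degenerates
the threshold to the mean and is flagged). The estimator is the ratio of
summed masked intensities per field (a per-cell mode was considered; summed
intensities are the default because wells are aggregated across images).
A known constant background can be subtracted from both channels before
summing. The corrected value divides by the green-channel throughput; the
red-channel throughput is shared by all constructs and cancels when
normalizing to the reference FP (which then reads exactly 1.00).

Maturation curves divide the masked green signal at every timepoint by the
red signal at the final (48-h) timepoint — the red reference matures late,
so per-timepoint division would distort the early phase — and correct for
throughput. "Signal" means summed masked intensity (masked-pixel area is a
plausible alternative; intensity is the default). A single-exponential
approach to plateau, value(t) = plateau·(1 − e^(−k·t)), is fitted by
least squares to estimate the maturation rate.

## Assays (`assays`)

OSER and Fluoppi scores are percentages of normal-looking (whorl-free /
punctum-free) cells among transfected cells scored; counting is manual (or
synthetic) and the score consumes count tables. A Wilson 95% interval is
attached as a precision aid — it is plumbing added by this package, not
part of the original scoring. Extended-focus projection and logarithmic
display transforms affect only what a human scorer sees, never the counts,
so they are not modeled.

pKa fitting uses F(pH) = F_max/(1 + 10^(h·(pKa − pH))); pKa is the pH of
half-maximal fluorescence and h the Hill slope. The fit refuses series
without a transition in range or with fluorescence decreasing in pH
(raising `FitError` instead of returning a silently wrong value).

Colocalization: Otsu thresholds are computed per channel on a 256-bin
histogram over the data range; a pixel is excluded if below threshold in
*both* channels (i.e., it survives if above threshold in at least one) or
saturated in *either*; Pearson's r is computed on the survivors, pooled
across z-slices. Thresholds are computed on unsaturated pixels only, so a
saturated mode cannot drag the Otsu split away from the background/signal
boundary. Note that excluding a saturated top tail truncates the joint
distribution and genuinely lowers r among survivors — the synthetic
saturation tests reflect this rather than hiding it.

## Motion maps (`imgdyn`)

For each consecutive frame pair (n, n+1) and each pixel, the NCC map holds
the Pearson correlation of the two window-local patches (means/SDs per
patch; zero-mean normalization). Local moments come from uniform box
filters with reflect (half-sample symmetric) padding — algebraically equal
to the naive per-pixel double loop, which serves as the test oracle at
1e-10 agreement. Zero-variance patches are undefined and returned as NaN.
The window is 7×7 by default (the measurement itself does not fix one) and
is recorded in the output; per-frame global means are subtracted before
filtering purely for numerical conditioning (Pearson is shift invariant).
`motion_summary` averages defined pixels in a region of interest over
half-open [start, end) time epochs, supporting before/after-drug
comparisons.

## Synthetic data (`simulate`)

What the generators emulate, and defaults chosen once as realistic for this
kind of experiment:

- **Spectra**: Gaussian excitation/emission shapes (σ_ex 25 nm, σ_em 20 nm
  in the analyses); only band integrals matter downstream.
- **Bleach traces**: mixtures of exponentials with additive Gaussian noise;
  unit initial intensity; true t₁/₂ analytic (mono) or by bracketed root
  finding on the exact mixture (multi).
- **Bicistronic fields**: cells are disks (radius 5 px) on a jittered grid
  (placement fails loudly if the image cannot hold n_cells without
  overlap); per-cell molecule counts are lognormal (μ 6, σ 0.5 — a heavy
  right tail typical of transient transfection); both channels share the
  count scaled by per-molecule brightnesses; constant background 10 plus
  Gaussian camera noise.
- **Maturation**: single-exponential approach to plateau (the simplest
  testable ground truth for a raw fluorescence-development curve).
- **Titrations**: the Hill model above plus Gaussian noise.
- **Assay counts**: Binomial(n_total, p_normal).
- **Colocalization pixels**: bivariate Gaussian mapped affinely to
  intensities (mean 1000, SD 100, so negativity is negligible); optionally
  a background population (uncorrelated, mean 50) that the Otsu filter is
  meant to remove, and an exactly ⌊f·n⌋-pixel saturated set (the jointly
  brightest pixels, ranked by channel A, set to the saturation value in
  both channels).
- **Motion stacks**: static (one smoothed texture repeated), shifting
  (integer-pixel periodic translation, exact by construction) and
  remodeling (per-pixel AR(1) noise with the stated frame-to-frame
  correlation). The remodeling texture is deliberately spatially white:
  windowed correlation of spatially smoothed fields is biased low in small
  windows (few independent samples per patch), which would break the
  analytic ground truth.

All randomness flows through one explicit integer seed (`numpy`
`default_rng`); identical parameters and seed give bit-identical output,
and every generator returns a ground-truth record for recovery tests.

**What passing on synthetic data does not show**: the generators contain no
point-spread function, no photon shot noise or camera gain model, no cell
morphology, no focus drift, and no detector nonlinearity (relevant at the
10,000 fps end of high-irradiance acquisition). Recovery results here
validate the estimators' arithmetic and statistical behavior, not their
robustness to real-microscope artifacts.

## Problem sizes in the test suite and analyses

The bundled analyses and acceptance checks run at desk scale: 100–120 noisy
traces for t₁/₂ recovery, 20 seeds × 192² px fields (60 cells) for
brightness recovery, 100 seeds for pKa recovery, 1,000 simulated counts for
Wilson-interval coverage, 32² stacks for the NCC oracle and 96² stacks for
remodeling recovery. These sizes give Monte-Carlo standard errors well
inside the asserted tolerances.

## Known limitations

- Published t₁/₂ values of real FPs require the original image data;
  the photobleaching stage is therefore validated by its defining
  invariants and synthetic recovery, not by reproducing those numbers.
- OSER/Fluoppi whorl/punctum *detection* is out of the primary path
  (scores consume count tables); confocal duty-cycle photobleaching and
  reversible photoswitching are not modeled.
- Whether the historical excitation average was lamp-weighted, and whether
  dim cells were excluded from assay denominators, are unknowable from the
  published description; the unweighted mean and unfiltered denominators
  are implemented.
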