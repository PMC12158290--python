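# Methods

This note documents the models, defaults and numerical choices behind
`pearspec`, and what the synthetic data can and cannot establish.

## The estimation problem

The SPAD value is a dimensionless relative-chlorophyll index measured by a
transmittance leaf meter; the pipeline estimates it from leaf reflectance
spectra *R(λ)* ∈ [0, 1] sampled on a uniform 1 nm grid (natively
350–2500 nm for a field spectroradiometer). Chlorophyll absorbs strongly in
the blue (~450 nm) and red (~670 nm), so reflectance there decreases with
chlorophyll content, and the red edge (~680–750 nm) shifts and steepens.
The statistical task is to find the few wavelengths whose (transformed)
reflectance correlates most strongly with SPAD and to calibrate an affine
predictor on them.

## Pipeline stages and defaults

**Smoothing.** Running median, window 5 bands, reflecting edges
(`scipy.ndimage.median_filter`, mode `reflect`; a `truncate` mode with
shrinking edge windows is also provided). The window is the smallest that
removes isolated single-band dust spikes while leaving the ~30 nm-wide red
edge essentially untouched. A median never leaves the input's [min, max]
envelope and is idempotent on constants, both enforced by tests.

**Analysis window.** 400–1075 nm by default: it contains the visible and
red-edge/NIR region where chlorophyll-sensitive bands occur, and trims the
noisiest extremes of the full grid. A full-range run is a config switch
(`window_nm=None`).

**Transforms.** 1/R and log₁₀R use a clip floor of 1e−4 on reflectance
(field spectra can touch zero after smoothing near the UV edge); clipped
band counts are logged. The logarithm is base 10, the spectroscopy
convention; the base only rescales downstream coefficients. Derivatives are
central differences over 2Δλ with the two endpoints dropped — symmetric and
standard for 1 nm grids.

**Haar DWT.** Orthonormal normalisation (pairwise sums/differences divided
by √2), three levels. Odd lengths at any level are padded by duplicating
the final value (half-sample symmetric reflection); this matches
`pywt.wavedec(..., 'haar', mode='symmetric')` coefficient-for-coefficient,
which the test suite uses as an independent oracle, alongside an explicit
perfect-reconstruction check. With orthonormal scaling, Parseval's identity
(input energy = coefficient energy) holds to rounding error on unpadded
lengths. Every coefficient is assigned the mean wavelength of the original
samples in its 2^j-wide support, pads excluded, so selected "sensitive
bands" are reportable in nm at every scale (level-1 coefficients sit at
half-nanometre midpoints).

**Band selection.** Pearson correlation (the models are linear; rank
correlation would answer a different question) of each band against SPAD.
Bands with variation at floating-point noise level are flagged and set to
r = 0 rather than producing NaNs. Selection is greedy max-|r| with a 50 nm
minimum separation and ties broken toward the shorter wavelength; the
separation prevents picking two near-collinear neighbours from one
absorption feature and reproduces the visible + red-edge pairing pattern
typical of two-band chlorophyll models. Greedy selection equals the
brute-force lexicographic optimum over separation-feasible subsets (the
first pick is the global argmax, each later pick the argmax among feasible
bands), which a test verifies by enumeration on small grids. Correlation is
computed on the modeling split only by default (`correlate_on="train"`), so
validation metrics are not informed by validation samples; correlating on
all samples is a config option.

**Split.** Seeded uniform random assignment without replacement, 60
modeling / 27 validation for 87 samples (the same ~69/31 ratio for other
sizes). The default seed, 20250605, is fixed and logged with every run.

**Models.** Predictors and response are z-standardized on the modeling
split by default, and coefficients are reported in standardized units: with
reflectance-scale inputs (~0.1–0.5) and SPAD-scale outputs (~46), raw
coefficients span orders of magnitude, whereas standardized ones are
comparable across transforms. The standardization constants are stored in
the model, predictions are always in SPAD units, and every serialized model
also carries the equivalent raw-unit affine form (`raw_affine()`);
`standardize=False` fits directly in raw units. Two-band OLS uses
`numpy.linalg.lstsq` on the (centered) design and rejects collinear or
constant predictor pairs by name. PLS is PLS1 by NIPALS: with a single
response each component's weight vector X′y/‖X′y‖ is closed-form, so no
inner iteration is required; components are extracted with deflation and
composed into an affine predictor. With as many components as the centered
predictor rank, PLS reproduces OLS exactly — a test pins this, plus
agreement with scikit-learn's `PLSRegression` to 1e−6. The pipeline's
default method is PLS with the component count chosen by leave-one-out RMSE
on the modeling split (ties to fewer components); the two-band OLS path
reproduces the classical printed-equation form. The LOO choice is the only
hyperparameter search performed.

**Metrics and winner.** R² = 1 − SS_res/SS_tot against the measured mean
(may be negative on validation; undefined and rejected for a constant
measured vector) and RMSE in SPAD units. The winner is the representation
with the highest validation R², ties broken by lower validation RMSE —
ranking on training metrics would reward the overfit derivative models.

## The synthetic generator

Reflectance is built additively:

    R(λ) = continuum(λ) − Σ_b s_b · SPAD · exp(−(λ−c_b)²/2w_b²)
           + smooth(λ) + dust(λ),  clipped to [0, 1]

* `continuum` — logistic step from the visible level (0.30) to the NIR
  plateau (0.45) across a red edge centred at 715 nm with width 15 nm.
* Wells at c = 450 nm (w = 40) and 670 nm (w = 30) with depth
  s = 0.003 reflectance per SPAD unit: at the SPAD maximum (~67) the well
  floor reaches ≈ 0.10, a realistic visible-band minimum for healthy
  leaves, and band reflectance is strictly decreasing in SPAD — the
  identifiability the recovery tests exploit.
* `smooth` — a random degree-4 Chebyshev polynomial per sample, scaled so
  the per-band SD is ≈ 0.004 at the grid edges (slightly lower
  mid-grid): broad, spatially correlated drift such as illumination or
  stray-light variation.
* `dust` — i.i.d. Gaussian per band, SD 0.002 by default (0.01 for the
  stress tests). Pure white noise by construction, so the wavelet transform
  provably routes it into the detail (H) series: the lever behind the
  low-frequency-stability property.
* SPAD: truncated-normal rejection sampling, N(45.8, 3.64²) on
  [32.6, 67.1]; the recorded label adds N(0, 1) meter error (the latent
  value generates the spectrum; labels are clipped back to the range).
  Direction labels (22/22/22/21 east/south/west/north) are bookkeeping
  only — direction does not influence the spectrum.

All randomness flows through one `numpy` generator seeded by `config.seed`;
identical configs are bit-reproducible.

**What the generator does not emulate:** radiative-transfer leaf optics
(PROSPECT-style), water/structure absorption features beyond the red edge,
canopy BRDF and direction-dependent illumination, instrument splice
artifacts, or correlated (non-white) dust noise. Consequently, passing
tests demonstrate that the pipeline recovers planted linear SPAD signal
under realistic noise magnitudes and that detail-scale models degrade under
white high-frequency noise — they do not certify accuracy on real orchard
spectra, where the SPAD–reflectance link is nonlinear and noise is
structured.

## Problem sizes in tests

The test suite and acceptance script run at the study scale (87 samples,
full 350–2500 nm grid at 1 nm) throughout; the stochastic property checks
use 50 replicates for band recovery and 20 seeds for the low-frequency
stability comparison (sign test at α = 0.05), sizes at which both effects
are decisive. The large-sample check of the SPAD moments uses 10,000 draws
on a truncated grid.

## Known limitations

* The two-band model assumes the SPAD signal is affine in the chosen band
  values; on real leaves the relation saturates at high chlorophyll.
* Greedy selection with a fixed 50 nm separation can miss a globally better
  non-greedy pair when |r| profiles are multi-modal at fine scales.
* Leave-one-out component selection on 60 samples is slightly optimistic
  relative to nested cross-validation.
* The median window (5) and clip floor (1e−4) are sensible defaults, not
  fitted quantities; both are configurable.
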