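# Methods

## Scope and data model

`fusiondry` models one drying experiment as a set of samples, each carrying
a hyperspectral reflectance cube (H×W×224, wavelength axis 397.66–1003.81 nm),
a 10-sensor e-nose steady-state vector, and a reference moisture content
(MC, mass fraction in [0, 1]; percentages only at presentation). Three
variable blocks per sample feed the models: the 224-band mean ROI spectrum,
26 image variables and the 10 sensor responses.

The instrument's true band centers are unpublished, so the wavelength axis
is 224 linearly spaced points between the published endpoints. Band lookup
is nearest-neighbor with ties breaking to the lower index; pixel coordinates
are 0-based, row-major, origin top-left.

## Synthetic generator

The generator emulates the statistical structure the analysis relies on, not
shrimp optics. It is first-class, tested code; its defaults are the study
conditions.

**Drying curve.** Expected MC is a falling logistic in time, normalized so it
passes exactly through `mc_start = 0.7275` at t = 0 and `mc_end = 0.1567` at
t = 12 h. No functional form is published for the curve, so the logistic was
chosen as the simplest smooth two-phase shape whose rate peaks at the
inflection; with `inflection_h = 4`, `scale_h = 2` the numerical drying rate
peaks at 4 h at ≈ 8.3 percentage points/h, matching the reported kinetics.
Replicates scatter around the stage mean with SD `replicate_sd = 0.012`
(≈ 1.2 percentage points, a plausible between-animal spread that keeps
adjacent late stages overlapping, as real replicates do).

**Cubes.** An elliptical foreground (axes 0.36/0.24 of the 96×96 default
frame, ±5% jitter) sits on a flat dark background (reflectance 0.05). The
noise-free foreground spectrum is closed-form:

    s(λ) = b(λ)·(1 − darkening·(1−MC)·w_vis(λ)) − (d0 + d1·MC)·Σ_b A_b·G(λ; c_b, σ_b)

with a sigmoid baseline b(λ) rising from 0.20 to 0.50 around 550 nm,
Gaussian absorption bands at 750 and 960 nm whose depth d0 + d1·MC is
strictly increasing in moisture, and a visible-range (≲700 nm) darkening
factor that deepens as the sample dries — giving the segmentation contrast
at 685.5 nm and the color-moment signal. Scattering artifacts are a
per-sample multiplicative gain (SD 0.08) and additive offset (SD 0.01) plus
white noise (SD 0.004); these are exactly the distortions SNV and derivative
preprocessing remove. Raw counts are synthesized as
`black + R·(white − black)` with flat reference frames, so the calibration
identities are exact. Default cube size is 96×96 px (configurable); the
pipeline-level tests use 48×48 and the statistical behavior is unchanged —
the ROI still contains thousands of pixels.

**E-nose.** A single volatile latent v = 1 − MC drives all sensors through
saturating Michaelis–Menten responses `base_i + amp_i·v/(K_i + v)`; three
amplitudes are negative (reducing-gas channels). Per-sample multiplicative
gain drift (SD 1.5%) and additive noise (SD 0.01) are applied on top.
Transient sampling curves are not simulated: the downstream pipeline only
consumes the steady-state vector. Because the responses are nonlinear in MC,
monotonicity is a rank (Spearman) property, not a Pearson-correlation one.

**What passing tests do not show.** The generator has one latent variable
(MC) behind every modality, no confounders (temperature, humidity, batch),
no sensor aging, and spatially homogeneous tissue. Pipeline performance here
is an upper bound; on real data the fusion ordering may compress and the
e-nose block is expected to be far less stable.

## Calibration and segmentation

`R = (raw − black)/(white − black)` per pixel per band; reference frames may
be per-band vectors or full frames. Noise can push R outside [0, 1], so
values are clipped to [0, 1.5] with the clipped fraction recorded; more than
5% clipping (or a white−black gap below 1e−6) aborts with the offending
bands named. No threshold value is published for the 685.5 nm segmentation,
so Otsu's parameter-free threshold is applied to the calibrated band (the
calibrated/raw choice is itself unstated; calibrated is used), the brighter
side is foreground, and the largest 8-connected component is kept.

## Image variables

Color moments use the population SD and the signed cube root of the third
central moment (the standard color-moment skewness convention; the source
gives no formula). A third moment smaller than 1e−12·sd³ is snapped to zero
before the cube root, which otherwise amplifies rounding noise. Texture is
computed from exactly the PC1 and PC2 score images of a mean-centered PCA
over the masked cube's foreground pixels (bands as variables), even when PC1
alone exceeds the 99% cumulative-variance target — two images, eight texture
values, matching the 26-variable block. Whether the published PCA ran on
spectral bands or on the RGB composite is ambiguous; spectral-band PCA is
used. GLCMs are quantized to 32 min–max levels over the mask, accumulated
symmetrically at distance 1 over the four directions, counting only pairs
with both pixels in the mask (background carries a reserved level that is
dropped before normalization); correlation of a zero-variance region is
defined as 0 (the 0/0 case).

## Preprocessing

SNV standardizes each row to mean 0 / sample (ddof = 1) SD 1. S-G windows
are unpublished: defaults are window 11, polyorder 2 for 224-variable
spectra and window 5 for blocks narrower than 11 variables (the 10-sensor
block), with polynomial-fit edge extension for same-length output. Recipe
names compose left to right ("FD-SNV" = derivative, then SNV); the
application order is not defined by the source and is exposed through the
recipe names themselves. Applying derivative recipes across the 10
heterogeneous sensors is implemented as specified but is of doubtful
physical meaning; the default model recipe for the e-nose block is plain SNV.

## CARS

The canonical scheme: at run i, fit a PLSR (latent variables chosen by CV,
capped at 10) on a random 80% sample subset restricted to the currently
retained variables; weight variables by normalized |b_j|; retain
ceil(r_i·p) of them by weighted sampling without replacement (zero-weight
variables can never survive), where r_i = a·e^(−k·i) is fixed so run 1
retains all p and run 50 retains 2; score each retained set by full-
calibration cross-validated RMSE. The winner is the minimum-RMSECV run, ties
breaking toward fewer variables. All hyperparameters (50 runs, 5 folds, 80%
sampling, max 10 LVs, seed) are exposed and logged in the run manifest. The
published selection counts (14/16/8) are data-dependent and are not
reproduction targets; the test surface is planted-variable recovery on
synthetic data.

## PLSR and evaluation

NIPALS on autoscaled X (centered, unit ddof=1 variance — the blocks mix
reflectance, moments and conductance ratios) and centered y. For a single
response the weight update is closed-form, and one deflation pass yields
coefficients for every component count 1..A, so cross-validation over LV
counts costs one fit per fold. Components stop early when the residual is
exhausted (tolerance 1e−12 on ‖X′y‖ and ‖t‖²). LV choice minimizes CV RMSE
over 1..10 with ties toward fewer components; CV folds are
contiguous-stratified by the response (each chunk of sorted neighbors deals
one sample per fold) so every fold spans the MC range and drying stages
cannot leak. Metrics: R² = 1 − SS_res/SS_tot per set, RMSE per set,
RPD = sample SD(y_val)/RMSEV (+∞ when RMSEV = 0). At full rank the fit
equals ordinary least squares, which the tests check against a
normal-equations oracle and sklearn's PLS implementation.

## Splitting and fusion

The published split counts (84 + 28 from 104 samples) are internally
inconsistent; the implemented default honors the 3:1 ratio systematically:
samples ranked by MC, one per period of 4 (mid-period offset) to validation,
extremes pinned to calibration — 78/26 for 104 samples. A seeded random
split is also available. One split is reused across all variants of a run
for comparability.

Pixel fusion concatenates the preprocessed blocks; feature fusion
concatenates only CARS-selected columns (role-prefixed labels keep
provenance and uniqueness). Decision fusion regresses calibration MC on the
per-block calibration predictions with an intercept — unconstrained OLS
(whether the published weights were constrained is unstated); a condition
number above 1e10 on the normal equations triggers a 1e−8 ridge fallback
with a warning, yielding the minimum-norm solution in the exactly collinear
case. Weights are fit on calibration predictions only and applied unchanged
to validation predictions.

Leakage discipline throughout: preprocessing is row-wise (stateless), CARS
and LV choice see calibration rows only, PLSR scaling uses calibration
statistics, fusion weights use calibration predictions. The audit test
perturbs validation rows and asserts every fitted parameter is bit-identical.

## E-nose exploration

PCA on the autoscaled sensor block plus Ward/Euclidean agglomerative
clustering (no linkage/distance is published; Ward is the standard default
for compact stage groups). With noise off the 13 stage centroids are
distinct and replicates identical, so a 13-cluster cut recovers stages
exactly; a 7-cluster cut is exact on a 7-stage design, but cutting the full
13-stage series at 7 clusters need not split on stage boundaries because
late-stage MC values nearly coincide.

## Problem sizes and budgets

Desk-scale defaults used by the test suite: 48×48-px cubes for full-pipeline
runs (104 samples, 10 seeds for the fusion-ordering check), 20 seeds of
n = 80, p = 100 planted-signal instances for CARS recovery, and a
26-sample dataset for unit-level pipeline tests. The complete suite runs in
about one minute on one CPU.

## Known limitations

* One latent variable drives all synthetic modalities; real drying has
  confounded kinetics (case hardening, fat oxidation) none of which are
  modeled.
* ENVI I/O covers the plain hdr dialect only (BSQ/BIL/BIP, common numeric
  types).
* The decision-fusion weights are unconstrained; negative weights are
  possible and meaningful only as regression coefficients.
* Reported study-specific values (Table-style metrics, selected wavelength
  counts, fitted fusion weights) depend on the unreleased raw data and are
  treated as qualitative anchors, not reproduction targets.
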