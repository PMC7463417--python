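# Methods

This note records the models, conventions, and numerical choices behind
`pettex`, in the spirit of a statistical methods appendix: what is computed,
under which assumptions, and where the genuinely open design choices were
settled.

## Study design being emulated

The pipeline reproduces a pretreatment PET/CT radiomics workflow for
primary gastrointestinal DLBCL: a 30-patient cohort (20 interim complete
responders, 10 non-responders, assessed on the Deauville 5-point scale
after 3–4 chemotherapy cycles), one analysed lesion per patient (the tumor
with the highest SUVmax), manual 3-D ROIs on PET and one 2-D ROI on the CT
section with the largest lesion area, a second reader for agreement
analysis, and clinical covariates (Lugano stage, IPI, intestinal
involvement, Ki67, GCB/non-GCB subtype). CR is defined as Deauville 1–3
with no FDG-avid marrow disease; the marrow flag defaults to `False`
because marrow involvement plays no role in the emulated cohort.

## Phantom and cohort generator

Each patient's PET volume is a spherical tumor of radius *r* on a uniform
background in a 48³ grid at 4 mm isotropic spacing (the reconstruction
voxel size of the emulated scanner protocol). Intratumor heterogeneity is
multiplicative log-normal noise with spatial structure: a standard normal
field is smoothed by a Gaussian kernel of width `correlation_length_mm`
(default 8 mm), restandardized to unit variance, scaled by
`heterogeneity_sd` — the SD of log-intensity — and exponentiated. Setting
`heterogeneity_sd = 0` yields an exactly constant tumor, which pins the
noise-free contracts (SD = 0, entropy = 0) in tests.

Group-level defaults are calibrated to the published cohort contrasts:

| parameter | CR default | non-CR multiplier | rationale |
|---|---|---|---|
| base intensity (grey units) | 4000 | ×1.6 | median grey level ≈ 4000 vs ≈ 7300 |
| tumor radius (mm) | 21.5 | ×1.75 | median volume ≈ 42 cm³ vs ≈ 226 cm³ (×5.4) |
| heterogeneity SD (log units) | 0.18 | ×1.8 | entropy higher / GLCM energy lower in non-CR |
| between-patient log-SD | radius 0.40, intensity 0.60, heterogeneity 0.20 | — | interquartile spreads of the published feature table |

The heterogeneity SD is deliberately small (max/median intensity ratio
kept near 2–3, as observed clinically): larger values produce implausible
hot spots whose 41% threshold excludes most of the tumor and invert the
MTV group contrast. Covariate probabilities (intestinal involvement 0.30
vs 0.70, stage/IPI/Ki67/subtype distributions) mirror the published
contingency rows; Deauville scores are drawn from the printed score mix
(CR 3:8:9 over scores 1–3; non-CR 3:7 over 4–5), so the classification
rule is exercised on a realistic score distribution.

The second reader's masks are stochastic morphological perturbations of
the first reader's: each inner-boundary voxel is dropped and each
outer-boundary voxel added independently with probability
`reader2_perturbation/2` (default 0.1 each). This produces ICC < 1 with
realistic structure — global metrics (SUVmax, volume) remain excellent
while boundary-sensitive shape statistics (skewness, kurtosis) degrade.
The CT "slice" is the central PET slice rescaled to an attenuation-like
window (20–80) with independent Gaussian noise (SD 3): a plausible 2-D
texture source, not an anatomical simulation.

Cohort generation is a pure function of its config (including the seed);
identical configs reproduce bit-identical cohorts.

What the generator does **not** emulate: gastrointestinal anatomy, scanner
physics (point-spread function, partial volume, reconstruction artifacts),
multi-lesion disease, or any real coupling between covariates and imaging.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis*, not clinical performance on real images; the published AUCs
cannot be reproduced without the original patients.

## Feature definitions

**Semiquantitative metrics.** SUVmax is the maximum masked intensity. MTV
is the volume of masked voxels *strictly greater* than 41% × SUVmax
(configurable fraction; ties at the threshold excluded, following the
"higher than" definition). The threshold is applied inside the supplied
ROI mask rather than an interactive workstation "cropping sphere" — the
sphere is an operator artifact that cannot be reproduced deterministically.
ROI volume is voxel count × voxel volume; the maximal diameter is the
largest Euclidean distance between masked voxel centers (in-plane for 2-D
masks), computed exactly via convex-hull pruning.

**First-order features** are computed on raw masked intensities: mean,
sample SD, min/max, linear-interpolated percentiles (5/10/25/50/75/90),
bias-uncorrected skewness g₁ and excess kurtosis g₂ (both feed rank tests,
which are invariant within any monotone family, so the estimator
convention is stated rather than fitted), and Shannon entropy (base 2) of
the binned histogram. Mode and max-frequency are computed on
integer-quantized grey levels, ties broken toward the lowest level.

**GLCM features.** Co-occurrences are accumulated per axial slice
(matching slice-wise ROI drawing; the CT case is a single slice) at
distance 1 in four in-plane directions labelled 10–13 for 0°/45°/90°/135°,
each counted symmetrically and normalized to sum 1. Both voxels of a pair
must lie inside the mask. From the normalized matrix *P* with 0-based bin
indices: entropy = −ΣΣ P log₂ P, energy = ΣΣ P², inertia (contrast) =
ΣΣ (i−j)² P, variance = ΣΣ (i−μ)² P with μ = ΣΣ i·P. Direction labels,
distance, symmetrization, and 2-D accumulation are all configurable.

**Grey-level discretization.** The generic default is 256 equal-width bins
over the ROI's own min–max range, a common radiomics convention under
which histogram entropy is invariant to affine intensity maps. The cohort
*analysis*, however, uses fixed per-modality ranges (PET 0–20480, CT
0–256, 256 bins): ROI-relative binning is scale-free, which makes entropy
and GLCM energy blind to the absolute grey-level spread of a lesion — and
empirically gives *lower* entropy for more heterogeneous tumors of the
same size, because multiplicative heterogeneity skews the distribution.
With a fixed range, hotter and more heterogeneous lesions occupy more
bins, so first-order entropy rises and GLCM energy falls with
heterogeneity — the sign pattern the response analysis relies on and the
direction observed clinically. Both policies are exposed on
`DiscretizationSpec`; the fixed ranges are wide enough that clipping into
the top bin is rare at the generator's intensity scale.

## Statistical procedures

All tests return a uniform `TestResult` (method, statistic, p, sidedness,
n/df, warning) serializable to JSON.

- **Fisher's exact test**: hypergeometric enumeration over all tables with
  the observed margins. Two-sided p sums the probabilities of tables no
  more likely than the observed one. One-sided p is the tail in the
  direction of the observed association, defined as 1 when the observed
  cell equals its independence expectation (no direction to test).
  Degenerate margins give p = 1 with a warning. The published CR-rate
  comparisons reproduce under the one-sided mode (verified for all five
  rows by enumeration), although the source declares two-tailed testing
  throughout — both modes are provided and the analysis default is
  documented rather than hidden.
- **Mann–Whitney U**: mid-rank ties with 0.5 credit; exact enumeration of
  all rank assignments when the pooled sample is ≤ 12 without ties,
  otherwise a tie-corrected normal approximation (no continuity
  correction, matching common asymptotic practice). One-sided p is the
  tail in the observed direction.
- **Wilcoxon signed rank**: zero differences dropped; exact enumeration of
  all 2ⁿ sign patterns for n ≤ 9, otherwise normal approximation with
  continuity and tie correction, reporting the signed Z.
- **Shapiro–Wilk**: Royston's AS R94 approximation (via scipy), valid for
  3 ≤ n ≤ 5000; constant samples are a domain error.
- **ICC(2,1)**: two-way random effects, absolute agreement, single
  measurement, from the ANOVA mean squares
  (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with qualitative bands at
  0.200/0.400/0.600/0.800. Two raters measuring the same continuous
  features on the same subjects is the canonical design for this form.
  Zero between-subject variance is reported as an error, not a number.
- **ROC**: empirical curve; AUC equals the tie-corrected U/(n₁n₂)
  (asserted to 1e-12 in tests); orientation auto-chosen so AUC ≥ 0.5;
  cutoff maximizes Youden J with ties broken toward higher sensitivity;
  cases are called positive strictly beyond the cutoff. The positive class
  is non-CR throughout.
- **DeLong**: placement-value covariance of two correlated AUCs;
  Z = ΔAUC/SE with a two-sided normal p; identical or perfectly
  rank-correlated markers return Z = 0, p = 1.
- **Logistic prediction probability**: unpenalized maximum likelihood via
  Newton–Raphson on internally standardized predictors (coefficients
  mapped back to original units), intercept included, convergence at
  relative log-likelihood change < 1e-10 or 100 iterations. Perfect or
  quasi-perfect separation (runaway standardized coefficients) is flagged,
  the fit marked non-converged, and the last iterate's probabilities still
  returned. The default panel is SUVmax, first-order entropy, ROI volume,
  and intestinal involvement.
- **Hosmer–Lemeshow**: deciles-of-risk grouping of predicted
  probabilities, χ² = Σ (O−E)²/E over both outcomes per group,
  df = groups − 2 (which presumes in-sample fitted probabilities — the
  calibration null in the tests therefore refits the model per replicate);
  groups with zero expected count are merged with a neighbor and warned.

## Feature selection and evaluation conventions

The univariate filter uses the *two-sided* Mann–Whitney test at α = 0.05
(the declared two-tailed convention; only the contingency analysis needs
one-sided mode to reproduce printed values). Constant features get p = 1
and a warning. Survivors are grouped into four categories — PET grey-level
location features (mean, mode, min/max, percentiles) as uptake intensity;
spread/shape features (SD, max-frequency, skewness, kurtosis) and CT
first-order features as grey-level distribution; volumes and diameters as
tumor size; first-order entropy and all GLCM features as heterogeneity —
and the lowest-p survivor per category is selected. Exact p ties are
broken toward the percentile/rank-type feature when normality is rejected
for a tied feature, otherwise toward the moment-type feature. SUVmax and
MTV bypass the filter and are always reported; MTV is excluded from the
size category (the manually contoured volume is that category's
candidate). Evaluation is in-sample, matching the emulated design (no
cross-validation); a holdout split is deliberately out of scope.

## Problem sizes and numerical choices

Simulation-backed tests use phantoms of 14³–24³ voxels and cohorts of
12–30 patients, with 300–500 replicates for calibration checks — large
enough for binomial error bands of ±3.3 SE around α = 0.05 to be
informative, and small enough that the whole suite runs in well under a
minute. Oracle-equivalence tests run on random ≤ 8³ phantoms against
literal double-loop/sorting/enumeration implementations kept in the test
tree, separate from the package. Per-patient seeds are spawned from the
cohort seed through a master generator, so any cohort is reproducible from
one integer. GLCM normalization is validated to 1e-9; AUC identities to
1e-12; the Newton solver regularizes its Hessian by 1e-12 only to guard
exact singularity.

## Known limitations

- The phantoms are spherical and single-lesion; diameter-based features
  are nearly deterministic given the radius, so their between-patient
  variance is optimistic compared with irregular tumors.
- Fixed-range discretization ties the entropy/energy scales to the
  generator's grey-level units; real scanners require choosing the range
  (or switching to ROI-relative binning) per protocol.
- ICCs from morphological mask perturbation quantify boundary sensitivity
  only; they cannot reproduce systematic human biases such as consistent
  over-contouring.
- The one-sided/two-sided testing discrepancy in the emulated contingency
  analysis is reproduced, not resolved; no multiple-testing correction is
  applied across the ~60 feature tests (an FDR column can be added by the
  caller), matching the emulated design.
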