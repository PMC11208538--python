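# Methods

This note documents the models, estimators, conventions, and design choices
behind `fmricomplexity`. It is the package's own account of its science; every
empirical number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Problem setting

Resting-state fMRI (rsfMRI) yields one BOLD time series per brain region
(ROI) after parcellation with an atlas. Two families of scalar, per-ROI
features are extracted and compared as predictors of behavioral phenotypes
against the three individual characteristics age, gender, and total
intracranial volume (TIV):

* **Temporal complexity**: Hurst exponent (HE), weighted permutation entropy
  (wPE), area under the type-B range-entropy trajectory (RangeEn_B AUC), and
  multiscale-entropy AUC (MSE AUC).
* **Functional connectivity**: eigenvector centrality (EC) and weighted
  clustering coefficient (wCC) on the ROI-wise Pearson connectome, and
  fALFF, local correlation (LCOR), and global correlation (GCOR), natively
  voxel-level measures averaged within ROIs.

Downstream, the package provides tSNR-based ROI selection, a four-scenario
confound-aware prediction engine with nested cross-validation, and a
feature-pair fingerprinting (identification) analysis. Because the cohort
data this design targets (≈ 490 time points at TR = 0.735 s per subject) is
access-controlled, a first-class synthetic-cohort generator with known ground
truth stands in for real data everywhere in the tests.

## Synthetic cohorts

Each ROI series is a sum of (i) loading-weighted shared latent signals
(fractional Gaussian noise, fGn), giving controllable inter-ROI correlation;
(ii) an independent per-ROI fGn with a per-subject, per-ROI Hurst exponent
drawn from `hurst_range`; and (iii) white noise with SD `roi_noise_sd`. The
fluctuation is demeaned and a constant offset is added so that mean/SD equals
the requested per-ROI tSNR *exactly* (this mirrors the tSNR definition used
for thresholding). Identical spec + seed reproduce the cohort bit for bit.

fGn is simulated **exactly** by Davies–Harte circulant embedding of the true
autocovariance γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}), with a Cholesky
fallback when the embedding is not nonnegative. Exactness matters: it makes
the Hurst-recovery checks a real parameter-recovery experiment rather than a
round trip through one approximation.

Covariate defaults emulate a late-middle-aged imaging cohort: age uniform on
45–80 years, gender balanced by construction (prediction subsampling is
always sex-balanced), TIV Gaussian with gender-dependent means (1350 ml
female / 1500 ml male, SD 110 ml) — typical published morphometry values.
Default per-ROI tSNR is 50, a realistic parcellated-rsfMRI magnitude.

**Targets.** No generative model links brain features to behavior in the
literature this package operationalizes, so targets are a deliberately simple
stand-in: a β-weighted sum of a named per-subject ground-truth map plus
covariate terms, standardized, plus Gaussian noise; binary targets threshold
the latent score at its median; a null target is independent of everything.
Two truth features are available: `"hurst"` (the per-ROI Hurst exponents —
recoverable by the HE extractor, but noisy at 490 samples) and
`"factor_coupling"` (a per-subject latent connectivity strength — tracked
with high precision by GCOR/EC), which is what the effect-recovery tests use.
Passing those tests shows the pipeline recovers planted linear effects under
these idealized conditions; it says nothing about effect sizes, nonlinearity,
motion, or physiological noise in real rsfMRI.

## Temporal-complexity estimators

**Hurst exponent.** Rescaled-range (R/S) analysis over ≥ 8 log-spaced window
sizes from 16 to n/2; each window is demeaned, R is the range of its
cumulative deviations, S its SD. The plain log–log slope of R/S is biased at
finite n (markedly so for anti-persistent series), so the estimator uses the
Anis–Lloyd–Peters correction: H = 0.5 + slope of (log R/S − log E[R/S]),
where E[R/S] is the analytic iid-Gaussian expectation per window size. With
this correction the estimator recovers H ∈ {0.3, 0.5, 0.7, 0.9} within ±0.1
(mean of 20 exact-fGn draws at n = 8192), and white noise maps to ≈ 0.5
without the upward small-sample drift of the uncorrected statistic.

**wPE** uses m = 4, τ = 1. Each embedded vector's ordinal pattern (stable
argsort, ties broken by order of occurrence) is weighted by the vector's
variance; the Shannon entropy of the weight-normalized pattern distribution
is divided by log₂(m!) so values lie in [0, 1]. Flat series (total weight 0)
return 0.

**Sample entropy** is −ln(A/B) with B/A the template-pair counts at lengths
m and m+1 within Chebyshev distance r·SD(x), self-matches excluded, both
counts over the same n − m template start points. Counting uses a k-d tree
pair count (O(1) memory), which the tests verify against O(n²) brute force at
n ≤ 300. Zero counts yield an explicit NaN marker, never an exception.
Tolerances are SD-relative, making all entropy features exactly invariant to
positive affine transforms of the input.

**RangeEn_B** replaces the Chebyshev distance by the normalized range
distance d = (max−min)/(max+min) of the component-wise absolute differences,
bounded in [0, 1]; identical templates (0/0) are defined as distance 0.
Because d ≤ 1, *every* pair matches at r = 1 and the value is exactly 0
there — the anchor the acceptance script recomputes. The feature used in
prediction is the trapezoidal AUC of the trajectory over a default grid of
20 equally spaced tolerances on (0, 1] (a config knob; the AUC is stable
within 2 % under 10× grid refinement).

**MSE** computes sample entropy of non-overlapping-mean coarse-grained
series at scales 1..τ_max = 10, with m = 2 and the tolerance fixed at
r = 0.5 × SD of the original series across all scales (the standard
multiscale convention; the source description gives r without units). The
feature is the trapezoidal AUC over scales divided by τ_max.

**Undefined points** (zero match counts at extreme tolerances or scales) are
dropped from an AUC and the area rescaled to the full abscissa span, with a
logged warning — this keeps AUCs comparable across ROIs whose noise levels
leave different numbers of defined points. Minimum series length is 32
(configurable); 490 samples is the design center.

## Connectivity measures

The connectome is the pairwise Pearson matrix of ROI series (symmetric, unit
diagonal; constant ROIs are an error naming the ROI). For the graph measures
negative weights and the diagonal are zeroed — Perron–Frobenius requires a
nonnegative matrix for a meaningful leading eigenvector, and the convention
for negative functional couplings is genuinely open; zeroing is the most
common choice and is isolated in one method (`FCMatrix.nonnegative_weights`).

* **EC** is the unit-norm leading eigenvector (symmetric eigensolver, sign
  fixed nonnegative); scale-invariant in the weights.
* **wCC** is the Onnela geometric-mean triangle intensity over weights
  rescaled by the global maximum, divided by k(k−1) for binary degree k;
  degree < 2 gives 0 by definition. Verified against exhaustive triangle
  enumeration (n ≤ 12) and networkx.
* **fALFF** is the amplitude (root-power) spectrum mass in 0.008–0.09 Hz over
  the total mass on (0, Nyquist], DC excluded; values in [0, 1] and
  amplitude-scale invariant.
* **GCOR** is each voxel's mean Pearson correlation with all other in-mask
  voxels, computed via normalized series so cost is linear per time point in
  the voxel count; self excluded (a flag includes it, shifting values by
  ~1/N_vox).
* **LCOR** is the Gaussian-kernel-weighted mean correlation with neighboring
  in-mask voxels, σ = FWHM/(2√(2 ln 2)) with FWHM = 25 mm by default,
  truncated at 3σ, self excluded, weights renormalized over available
  neighbors at mask edges. The implementation is pairwise and targets the
  modest synthetic volumes used here, not whole-brain grids.
* **parcellate** averages a voxel map within each ROI, ignoring NaN markers;
  an ROI with no defined voxel is an error.

On parcellated-only input the pipeline substitutes the voxel-free analogs:
fALFF on each ROI's mean series, and an ROI-level GCOR (mean correlation of
an ROI with all other ROIs). LCOR is only defined with voxel data.

Feature maps keep their physical scales at extraction; any z-scoring happens
inside the prediction engine, fold-wise.

## tSNR selection

Per-ROI tSNR is mean/SD of the series. Subject profiles are divided by their
own maximum ("normalized over ROIs" read as divide-by-max, so thresholds are
percent-of-maximum; min–max scaling would break the 0 % → all-ROIs endpoint),
averaged across subjects, and renormalized. Suprathreshold ROIs at level L %
are those with value **strictly** greater than L/100 — the strictness makes
both printed endpoints hold simultaneously (0 % keeps every ROI, 100 % keeps
none). The group map is computed once on the full cohort and reused at every
sample size; this follows the analysis design it reproduces and is a known,
deliberate data leak of a descriptive (not predictive) quantity.

## Prediction engine

Four scenarios: features raw (S1), features with age/gender/TIV removed
(S2), features + characteristics concatenated (S3, n_roi + 3 columns),
characteristics only (S4, 3 columns). Confound removal in S2 is at the
**target** level for regression and the **feature** level for classification,
always by OLS with intercept fit on training rows only.

Models: ridge with the penalty grid-searched over 39 values
(0, 1e-5, …, 1e6; 0 falls back to pseudo-inverse least squares), and a linear
SVM whose cost is the heuristic C = 1 / mean row Euclidean norm of the
z-scored training design (no search). Ridge classification is least squares
on ±1 labels with a sign decision.

Evaluation is 5 repeats of 5-fold nested CV (inner loop also 5-fold, a
config knob). Within each outer fold, confound removal and z-scoring are fit
on outer-train rows and applied to the held-out fold; the inner grid search
repeats both inside its own folds. Scores are the Spearman correlation
(regression) or balanced accuracy (classification) per outer fold, averaged
over the 25 repeat × fold pairs. Constant predictions score 0 with a logged
flag. The leakage audit tests recompute the training-row statistics
independently and check exact orthogonality/standardization on train and its
generic absence on test.

Sample-size sweeps draw seed-deterministic sex-balanced subsamples (per-cell
seeds derived by CRC32 from the master seed and the cell coordinates) and run
the full factorial feature × target × size × tSNR-level grid per scenario and
model, recording failed cells without aborting. The default size grid is
100→2000 by 50 and 2500→20000 by 500 — 75 distinct sizes; the printed count
of "78 population sizes" in the source analysis does not follow from its own
stated increments, so the grid is configurable and the discrepancy is
documented here rather than resolved. The grid enumerator is a separate,
countable step: 9 features × 4 targets × 78 sizes × 13 levels = 36 504 cells
per model type, and 9 × 1 × 78 × 13 = 9 126 for a single binary target.

## Identification (fingerprinting)

Each subject's map of feature X is matched to the subject whose feature-Y map
has the highest Pearson correlation across ROIs; accuracy is the proportion
of self-matches. Both directions are computed and the headline number is
their mean (the adapted fingerprinting literature averages directions).
Confound removal here is whole-sample per-ROI OLS — the analysis is
descriptive. Exact argmax ties count as misses (conservative; measure-zero
under continuous noise). Constant maps exclude the subject with a warning.
Accuracy is invariant to per-subject positive affine map transforms, degrades
with added map noise, and decreases with population size at fixed noise —
all verified on synthetic maps.

## Problem sizes in the test suite

The default test run exercises: Hurst recovery at n = 8192 × 20 seeds × 4
H values; the closed-form sample-entropy check at n = 100 000 (k-d tree
counting); pipeline properties on cohorts of 200–1000 subjects with 8–20 ROIs
and 150–490 time points, with a 5-value ridge grid for the statistical
property tests and the full 39-value grid for the 500-subject
effect-recovery run. These sizes were chosen so the complete suite is a
few minutes of single-core compute while keeping every statistical check
comfortably powered.

## Known limitations

* The brain–behavior coupling in the generator is linear and homoscedastic
  by construction; real effect structures are unknown and surely weaker.
* No motion, physiological noise, or scanner drift is simulated; tSNR is the
  only noise axis.
* LCOR's pairwise implementation is quadratic in voxels — appropriate for
  synthetic volumes, not for whole-brain data.
* The R/S Hurst estimator, although debiased, retains a mild attenuation
  toward 0.5 at H close to 1 (≈ −0.08 at H = 0.9, n = 8192) and larger
  spread at the 490-sample design center; HE-driven targets are accordingly
  harder to recover than connectivity-driven ones.
* Suprathreshold ROI counts for specific published atlas tSNR maps can be
  recomputed by `read_tsnr_profile_nifti` + `suprathreshold_counts` only
  when those maps are supplied by the user; they ship with no atlas data.
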