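# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `melrad`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Stage-IV melanoma patients starting first-line checkpoint inhibition carry
many metastases visible on the baseline staging CT. The question the
pipeline addresses: do quantitative image features of those lesions
(radiomics), aggregated over the whole body, add predictive value for
three binary endpoints — objective response at three months, and overall
survival at six and twelve months — beyond routine clinical covariates
(age, sex, primary-site and histology categories, BRAF status, LDH and
S100 serum markers, metastatic spread indicators, therapy type)?

## Synthetic cohort generator

No patient-level data of this kind can ship with the package, so
`melrad.synth` generates cohorts whose marginal statistics match a typical
262-patient first-line registry cohort:

* **Covariates.** Sex 42% female; age ~ N(68, 16) clipped to [25, 95]
  years (median ≈ 70, IQR ≈ 22); six primary-site and seven histology
  levels, BRAF/LDH/S100 binaries and their missingness, therapy mix 56%
  PD-1 mono / 44% PD-1+CTLA-4, all at their published frequencies.
* **Lesion burden.** Per organ, a zero-inflated negative binomial: a
  patient is affected with the organ's prevalence (e.g. lung 157/262,
  liver 79/262) and then carries 1 + NB lesions with the organ's mean
  count among affected (lung ≈ 17.4, liver ≈ 14.2, ...), reproducing both
  patient prevalences and lesion totals (≈ 24.4 lesions/patient overall).
  Volumes are log-normal per organ (medians ≈ 0.7–1.6 cm³, sd ≈ 1 on the
  log scale) — right-skewed, as tumour volumes are; the per-organ volume
  law is a generator default, not an external calibration. Every patient
  has ≥ 1 lesion (lesion-free patients are excluded from such studies).
* **Outcomes.** A clinical prognosis score eta is linear in the covariates
  (default log-odds of a good outcome: LDH −0.6, S100 −0.4, >3 organs
  −0.4, cerebral −0.3, hepatic −0.3, −0.1 per age decade, +0.2
  combination therapy — modest, plausible magnitudes chosen once).
  Response is logistic in eta with the intercept calibrated to a 37.3%
  response rate among evaluable patients; CR:PR and SD:PD splits follow
  the published mix. The latent radiomic risk factor z is standard normal
  and separated between responders and non-responders by the configured
  standardized effect d (`radiomic_effect`), so that with zero clinical
  effects the AUC of z against non-response is exactly the binormal
  Phi(d/sqrt 2) — the closed form the tests verify by pair counting.
  Overall survival is exponential with log-hazard −eta + d·z and base rate
  calibrated so the marginal median OS is 22.1 months; administrative
  censoring is uniform on 3–36 months of follow-up and produces the
  missing six-/twelve-month survival flags. The default d = 0.3 encodes a
  weak radiomic signal, matching the order of magnitude of effects such
  cohorts show.
* **Lesion images.** Each lesion is an ellipsoidal mask (random
  axis ratios within ±25%, volume-preserving) on a 3×3×3 mm grid (the
  study-typical reconstruction), voxelized boundary-inclusive; patch side
  = lesion extent + 6 voxels. In-mask intensity = organ-specific base HU
  + 10·z + white noise of sd 8·exp(0.2 z) + a smooth (sigma = 1 voxel)
  texture field of sd 6·exp(0.3 z); background is a noisy organ plateau.
  Thus the latent factor moves both the first-order statistics and the
  texture features monotonically — the simplest mechanism radiomics can
  detect.

**What the generator does not emulate:** organ anatomy, scanner and
reconstruction-kernel effects (the pipeline deliberately performs no
harmonization), lesion-shape irregularity beyond ellipsoids, spatial
correlation between lesions, informative censoring, and the dependence
structure between organ-involvement covariates ("">3 metastatic organs""
is drawn from its marginal, independent of the per-organ lesion draws;
hepatic metastases are tied to liver lesions). Passing tests on this
cohort therefore demonstrate the correctness and statistical calibration
of the analysis machinery, not clinical performance on real CTs.

## Feature extraction

The 1316-entry schema is 14 shape features plus, per image type
(original, LoG sigma = 1…5 mm, 8 stationary-wavelet sub-bands), 18
first-order and 75 texture features (24 GLCM, 16 GLRLM, 16 GLSZM, 14
GLDM, 5 NGTDM), following the IBSI-style definitions. Numerical choices:

* Texture discretization uses a fixed bin width of 25 HU-equivalent
  units anchored at the in-mask minimum — the common CT default; the
  same width feeds the histogram-based first-order entropy/uniformity.
* GLCM: distance 1, symmetric, features averaged over the 13 unique 3-D
  directions; directions without an admissible voxel pair are skipped.
  Degenerate single-gray-level matrices use the conventions
  Correlation = MCC = 1, InverseVariance = 0.
* GLRLM is likewise direction-averaged; GLSZM zones and GLDM dependence
  use the full 26-neighbourhood (GLDM alpha = 0: equal level).
* LoG filtering is scale-normalized (multiplied by sigma², sign-flipped
  so bright blobs respond positively) with sigma converted to voxels per
  axis; the wavelet is a single-level stationary `coif1` transform,
  symmetric-padded to even dimensions and cropped back.
* Shape: mesh volume and surface from marching cubes on the zero-padded
  mask; axis lengths from the PCA of physical voxel centres; maximum
  diameters from convex-hull vertices (projected per plane for the 2-D
  variants).
* Degenerate inputs: a single-voxel mask yields shape and first-order
  values but NaN for all texture features; NaN is the documented missing
  sentinel and is median-imputed inside the per-fold preprocessing.
  Constant regions set skewness/kurtosis to 0 (0/0 convention).
* No resampling by default (generated patches are isotropic); real-data
  mode offers isotropic resampling, linear for intensities and
  nearest-neighbour for masks. Features are not harmonized across
  scanners by design.

## Aggregation

Lesions are ranked (a) by volume and (b) by organ predictiveness tiers
(liver > adrenal gland/heart/spleen > skeletal > lung > lymph nodes >
soft tissue/skin, with the unplaced "other" category last) and volume
within tier; ties break by lesion id so the order is total and
deterministic. Schemes 2/4 are volume-weighted means over the top three
(all available if fewer); NaN sentinel entries drop out of the weighted
mean per feature. Burden volumes are mask-voxel-count × voxel volume in
mm³, summed in lesion-id order for exact permutation invariance.

## Selection, models, evaluation

* FCBF runs on the radiomic block only; clinical features always enter.
  Entropies are base 2; the relevance threshold delta defaults to 0 (any
  positive sample SU qualifies); relevance ties break alphabetically; the
  predominance comparison SU(p, q) >= SU(q, class) carries a 1e-12
  epsilon so exact mathematical ties are not decided by floating-point
  noise. Discretization reads "between −0.5 and 0.5" as the closed
  interval mapping to 0.
* The classifier is scikit-learn's `ExtraTreesClassifier` with default
  hyperparameters, 100 trees, row bootstrapping enabled, seeded per fold.
  No hyperparameter tuning, by design.
* Folds are unstratified random partitions; a repetition whose training
  folds would be single-class is redrawn with a shifted seed and logged.
  The preprocessor floor for zero-variance features is sd = 1e-12.
* The AUC point estimate is the plain mean over repetitions of the pooled
  out-of-fold AUC (tie half-credit). The 95% CI is a percentile bootstrap
  (simplest method consistent with resampling): B patient-index resamples
  drawn once, reused across repetitions and across the two models being
  compared; single-class resamples are redrawn with a cap. The mean ROC
  interpolates TPR linearly on a 101-point FPR grid per repetition,
  averages over repetitions per bootstrap sample, and takes pointwise
  2.5/97.5 percentiles; the mean curve is monotonized by a running
  maximum.
* Risk groups come from repetition 0's out-of-fold 12-month-survival
  scores at the 0.5 threshold (score < 0.5 = predicted non-survivor =
  high risk); out-of-fold scores are the only leakage-free choice.
  Kaplan-Meier and the two-group log-rank test (chi-square, 1 df; events
  before censorings at ties) are delegated to `lifelines`.

## Problem sizes of the shipped experiments

Simulation-based tests and the acceptance script choose cohort scales
that keep a single-CPU run short while leaving the statistics conclusive:
the coverage and signal-recovery experiments use n = 200 patients over 20
generator seeds with the lesion-count scale at 0.2 and the original-image
107-feature schema (the planted intensity/texture signal lives on the
original image, so the reduced schema loses no power); the bootstrap uses
B = 500 there; the signal-recovery CV uses R = 3 repetitions (and R = 1
for the stratification direction check). The acceptance script's
end-to-end demonstration runs n = 120 patients at lesion scale 0.3 with
the full 1316-feature schema, R = 10, K = 5, B = 1000.

## Known limitations

* **CI coverage for trained models.** Bootstrapping the fixed out-of-fold
  scores quantifies the rank-statistic (patient-sampling) variability
  only. A flexible model trained and validated within one finite cohort
  also inherits that cohort's chance covariate–label association, so the
  interval understates the variability of the CV estimate around the
  population AUC and undercovers under the null (the test suite measures
  ~75% instead of the nominal ~95% at n = 200; the same machinery is
  nominal when scores are exogenous). This is a property of the CI
  procedure itself, worth keeping in mind when reading non-overlap of
  such intervals as significance.
* Selection counts and selected-feature identities vary across folds —
  radiomic features are strongly correlated and near-interchangeable —
  so no stable single-feature biomarker should be read out of the FCBF
  logs.
* The synthetic image model is deliberately minimal; absolute AUC values
  on synthetic cohorts depend on the planted effect sizes and are not
  clinical estimates.
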