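# Methods

This document describes the generative model, the feature definitions and
their conventions, the reliability screen, the classifier, and the
evaluation machinery implemented in `renotex`, together with the rationale
for the main numerical choices.

## 1. Synthetic cohort generator

### 1.1 Why synthetic

The pipeline targets a clinical question — predicting WHO/ISUP nuclear
grade (low = I–II, high = III–IV) of clear cell renal cell carcinoma from a
single-slice CT texture analysis — for which the original imaging archive
cannot be redistributed. Instead of shipping an untestable pipeline, the
package includes a seeded phantom generator whose *group-conditional
distributions* are calibrated to the published cohort summary (264
patients: 206 low, 58 high grade; per-group tumor sizes, pre-contrast
density, and contrast enhancement). Every downstream claim (feature
correctness, reliability behavior, classifier ordering, CI coverage) is
then verifiable against either analytic ground truth or a brute-force
oracle.

The generator is a *statistical stand-in*, not an anatomical simulator.
Its job is to produce images whose measurable group statistics match the
published table and whose texture differs by grade in a controlled,
dial-able way — not to look like real CT slices.

### 1.2 Phantom model

Each phantom (`renotex.phantom.generate_phantom(grade, seed, params)`) is a
2D axial patch, default 128×128 px at 1.0 mm isotropic in-plane spacing,
containing:

1. **Geometry.** An ellipse with half-axes drawn from the group-conditional
   size distributions (transverse, anteroposterior; the craniocaudal extent
   is drawn but only recorded as a traditional measurement since the
   phantom is single-slice), random orientation, centered with jitter. The
   binary tumor mask is the ellipse interior.
2. **Background.** Renal parenchyma background at a fixed mean HU with
   mild Gaussian noise; the tumor is composited on top, so mask dilation
   during reliability perturbation picks up genuinely different tissue.
3. **Texture.** A stationary Gaussian random field (white noise convolved
   with an isotropic Gaussian kernel of correlation length `corr_len`,
   scaled to the group texture SD) added inside the tumor. Higher-grade
   parameters use a shorter correlation length and larger SD, giving
   busier co-occurrence statistics.
4. **Necrosis.** High-grade phantoms receive 1–4 hypodense blobs (smoothed
   thresholded noise, fraction of tumor area bounded in [0.03, 0.35]);
   low-grade phantoms are solid. The necrosis mask is recorded.
5. **Density calibration.** A per-patient mean pre-contrast HU is drawn
   from the group Normal distribution; the composite tumor interior is
   re-centered so the *whole-ROI in-mask mean of the pre-contrast image
   equals that draw exactly*. This makes the generator's group mean equal
   to the published group mean by construction, up to sampling error of the
   per-patient draws — which is what the calibration acceptance targets
   check.
6. **Enhancement.** The post-contrast image equals the pre-contrast image
   plus a per-patient enhancement constant (group-conditional Normal)
   applied to the *solid* (non-necrotic) tumor only, plus fresh acquisition
   noise. Necrosis does not enhance, which is the radiological rationale
   for including it.

All distribution parameters live in `renotex.params` as pydantic models
(`GroupParams`, `HeterogeneitySpec`, `default_params()`), in physical units
(mm, HU), and can be overridden wholesale — the tests use this to run
"dial" experiments (e.g. widening only the pre-contrast HU gap and
verifying that classifier validation AUC rises).

### 1.3 Cohort and split

`generate_cohort(n_low, n_high, seed)` draws independent per-patient seeds
from a `numpy.random.SeedSequence` (recorded in the truth table, so any
patient is regenerable in isolation) and returns the truth table plus
phantoms. The train/validation split is stratified: the global training
count is `round_half_up(ratio * n)` and per-stratum counts are allocated
by largest remainder, so the default 264-patient cohort always splits
198/66 with 155 low + 43 high in training. Singleton strata go to training
with a warning rather than crashing.

## 2. Gray-level discretization

Features that need discrete levels operate on
`renotex.imaging.discretize(image, mask, n_bins=256)`:

* window = in-mask mean ± 3 × in-mask SD (population SD);
* values are clipped to the window and floor-mapped to integer levels
  1..`n_bins` (the window upper edge maps to `n_bins`, not `n_bins`+1);
* a constant ROI (SD = 0) maps to the mid level `ceil(n_bins / 2)`;
* pixels outside the mask are level 0 and excluded everywhere.

The mapping is invariant to affine intensity transforms with positive
slope, which the tests assert directly.

## 3. Texture features (340)

The registry (`renotex.texture.registry`, also shipped as packaged JSON)
defines exactly 340 named features; `extract_all(image, mask)` returns
them in registry order. Conventions shared by all families: features are
computed on the discretized ROI; probabilities are normalized over in-mask
content only; entropies use log base 2; ROIs too small or degenerate for a
family yield documented sentinel values rather than NaN surprises.

* **Histogram (11).** Mean, variance, skewness, kurtosis (excess,
  population moments) of in-mask discretized levels, plus percentiles
  1/10/50/90/99 computed by the nearest-rank rule
  `x_sorted[max(1, ceil(p/100 · n)) − 1]`.
* **Absolute gradient (5).** Central-difference gradient magnitude over
  interior pixels (both 4-neighbors in-mask); mean, variance, skewness,
  kurtosis, and the fraction of nonzero gradients.
* **Autoregressive model (5).** A causal AR model with the four
  neighbors (W, NW, N, NE) and an intercept, fitted by ordinary least
  squares with per-column centering; features are θ₁..θ₄ and the residual
  SD. Because an intercept is fitted, θ is invariant to affine intensity
  rescaling — the recovery tests exploit this by synthesizing exact
  recursive AR fields and asking for θ back at 1e-6.
* **GLCM (275).** Gray-level co-occurrence matrices for distances 1–5 and
  directions 0° (0,1), 45° (1,1), 90° (1,0), 135° (1,−1), accumulated
  symmetrically and normalized; only pairs with both pixels in-mask count.
  Eleven features per matrix (angular second moment, contrast,
  correlation, sum of squares, inverse difference moment, sum average,
  sum/difference entropy and variance, entropy), reported per direction
  and as the 4-direction average (`avg`), 11 × 5 × 5 = 275.
* **GLRLM (20).** Run-length matrices in the same 4 directions; a run is
  a maximal constant-level segment along the direction, broken by the mask
  boundary. Five features per direction: short-run emphasis, long-run
  emphasis, gray-level nonuniformity, run-length nonuniformity, fraction
  of image in runs.
* **Wavelet (24).** Haar DWT (periodization mode) applied iteratively to
  the mask bounding-box patch (out-of-mask pixels filled with the in-mask
  mean to avoid edge artifacts); per scale 1–6, the mean squared
  coefficient (energy) in the LL, LH, HL, HH subbands. The first letter
  names the row filter. Scales whose input patch is smaller than 2×2 are
  invalid and report the documented sentinel (0 with a validity flag in
  the long-form feature table).

`feature_table(phantoms, ...)` assembles the 340-column per-patient
matrix; `traditional_features_table` adds the radiological block
(three diameters in cm, pre-/post-contrast density, enhancement, T stage).

## 4. Reliability screening (ICC)

Real studies re-contour ROIs to screen features for reader robustness.
Here, second readings are simulated by `perturb_mask` (distance-transform
based dilation/erosion with random magnitude; Dice against the original is
monotone in the perturbation). For each feature, agreement across readings
is summarized by the intraclass correlation from a two-way ANOVA. The
reliability report uses **ICC(2,1)** (single rater, absolute agreement,
readers random) for both intra- and inter-observer tables by default;
**ICC(3,1)** (consistency, readers fixed — systematic reader offsets do not
count against agreement) is available via the `model`/`icc_model`
arguments. Both are computed from mean squares directly and cross-checked in tests
against `pingouin` and a brute-force ANOVA oracle. Features are banded
(poor/fair/moderate/good/excellent at 0.2/0.4/0.6/0.8) and retained when
ICC > 0.75 (strict inequality), mirroring common radiomics practice. The
pipeline's reliability stage reports all 340 features for a sub-sample of
subjects and gates the texture block accordingly.

## 5. Classifier: LASSO + RF → SVM stacking

`renotex.modeling.StackedGradeClassifier` is a scikit-learn–style estimator
(`fit`/`predict`/`decision_function`/`get_params`/`set_params`, fitted
attributes with trailing underscores, clonable) with positive class
`"high"`. Per feature block (texture; traditional):

1. columns are standardized with *training-set* statistics (constant
   columns dropped);
2. a LASSO-penalized logistic regression is fitted with
   `LogisticRegressionCV` (liblinear, penalty grid C ∈ logspace(−3, 2),
   folds clamped to the minority-class count) and its linear score is the
   block's "signature";
3. a random forest is fitted in parallel;
4. a linear SVM (SVM1 for texture, SVM2 for traditional) combines the
   LASSO score and the forest probability into a block score.

SVM3 then stacks the two block scores. To avoid the optimistic bias of
training a combiner on in-sample first-level scores, the first-level
scores fed to the SVMs are **cross-fitted** (out-of-fold LASSO scores,
out-of-bag forest probabilities) by default; `naive_stacking=True` restores
the plain in-sample recipe for comparison, and the tests verify both that
it reproduces in-sample scores exactly and that it differs from the
cross-fitted default. The decision threshold is chosen on training scores
by the Youden index (max sensitivity + specificity − 1; lowest score among
ties), and `predict` applies `score ≥ threshold`.

The penalty grid is bounded above at C = 100 because liblinear on
near-separable standardized radiomics blocks burns its full iteration
budget at very weak penalties without changing the selected feature set;
the bound is a runtime/robustness choice, not a tuning knob (selection and
chosen C are unchanged on the default cohort).

## 6. Evaluation

* **AUC** is the exact rank (Mann–Whitney) statistic with tie handling.
* **Bootstrap CI** (`auc_ci`, default): stratified BCa bootstrap via
  `scipy.stats.bootstrap`, resampling the positive and negative score
  samples independently (which is what stratification means for AUC), with
  a vectorized rank-AUC statistic. BCa was chosen over the simpler
  percentile interval because a 500-simulation calibration study at n=200
  and true AUC 0.8 put percentile coverage near 0.92 — below nominal —
  while BCa achieved ≈0.95. When BCa's bias correction is undefined
  (e.g. perfectly separated scores), the percentile interval over the same
  bootstrap distribution is used; endpoints are clipped to [0, 1].
* **DeLong CI** (`method="delong"`): the asymptotic structural-components
  variance estimate, available for comparison and for large-n use.
* **Operating-point metrics**: sensitivity, specificity, PPV, NPV, and
  cohort-level false-negative/false-positive rates at the Youden threshold.
* **Group comparisons** (`compare_groups`): chi-square *without* continuity
  correction for categorical variables, Welch/Student t or Mann–Whitney
  (no continuity correction, exact where possible) for continuous ones —
  matching the conventions of the clinical-table statistics being
  reproduced.
* **Correlation maps**: Spearman by default, for feature-redundancy
  inspection.

## 7. Numerical conventions

* Entropies use log₂; `0·log 0 = 0`.
* Population (biased) variance and moments in histogram/gradient features.
* Percentiles use the nearest-rank definition (see §3).
* All randomness flows through `numpy.random.default_rng` /
  `SeedSequence`; every public entry point takes an explicit seed, and all
  seeds are kept below 2³¹ for portability.
* The pipeline writes a manifest with per-file checksums; a rerun
  recomputes only stages whose inputs, configuration, or outputs changed,
  and regenerates everything downstream of a change.

## 8. Verification strategy

The test suite deliberately avoids checking the package against itself:

* every texture/statistics kernel is compared on ≥100 random small
  instances against an explicit-loop brute-force oracle in
  `tests/oracles.py` that shares no code with the package (tolerance 1e-10,
  1e-12 where exact);
* worked micro-examples with hand-computed values pin each family's
  conventions (e.g. a 2×3 GLCM, a single run-length row, constant-patch
  wavelet energies);
* parameter-recovery tests (AR θ at 1e-6 on noise-free fields; LASSO
  selecting planted informative features in ≥90% of seeded cohorts)
  validate the modeling path;
* qualitative "dial" tests verify that turning a single generator knob
  (texture correlation length, pre-contrast HU gap) moves the downstream
  statistic in the predicted direction;
* a 500-simulation coverage study checks the bootstrap CI against its
  nominal level, and a permutation test checks that the classifier's null
  AUC is chance-level.

## 9. Limitations

* Phantoms are 2D, single-slice, and statistically — not anatomically —
  realistic; absolute AUCs on synthetic cohorts (often near 1.0 for the
  texture block) should not be read as clinical performance, only the
  *relative* behaviors (stacking ≥ best block, chance-level null,
  calibration of CIs) transfer.
* The necrosis model is a smoothed-noise blob, not lesion biology.
* Reader variability is simulated as geometric mask perturbation only; no
  inter-scanner or reconstruction-kernel effects are modeled.
* The traditional block's T stage is derived from size alone (T1/T2
  boundary at 7 cm), ignoring invasion criteria.
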