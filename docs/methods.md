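# Methods

## Problem and model

The pipeline classifies single 2-D T2-like fetal brain slices as healthy
or abnormal from texture alone. Its working hypothesis is that focal
abnormalities alter second-order intensity statistics — co-occurrence
structure, wavelet band energies, oriented frequency content — inside a
sub-region of the brain (here the upper-right quadrant of the brain
bounding box, the "minor ROI"). Nothing in the pipeline uses shape or
anatomical priors beyond the segmentation geometry; the classifiers see
only texture descriptors.

## Segmentation

Six steps, each exposed as a function and retrievable as an intermediate:

1. **Adaptive thresholding.** Foreground where
   `I(i,j) ≥ mean(window) + offset`. The window is clamped to lie fully
   inside the image (shifted at the edges, never padded), so a
   window as large as the image degenerates to global-mean thresholding.
   Defaults: window = nearest odd to side/8, offset = 2% of the dynamic
   range, floored as if the range were one gray level so constant images
   produce an empty foreground and fail fast.
2. **Opening** with a disk of radius 1 removes thin links between skull
   and maternal tissue. Erosion/dilation treat pixels outside the image
   as background (`border_value=0`); this is the fixed convention for all
   morphology here. Under it, the closing/opening duality
   `close(A) = ¬open(¬A)` holds exactly away from the image frame, which
   is how the property is tested (random masks with a zeroed 2-px frame).
3. **Border clearing** removes every 8-connected component touching the
   frame (the maternal band by construction touches it).
4. **Closing** with the same element fills small skull gaps. Using a
   different element than the opening triggers a warning, since the pair
   is meant to be morphologically matched.
5. **Boundary tracing + watershed.** Components are organized into parent
   (outer) and child (hole) contours, sorted by descending enclosed area.
   The region image rasterizes the *filled* parents — this is the step
   that turns the thresholded skull outline into a solid brain candidate.
   The watershed then runs on the distance transform of that region
   image: markers are the extended minima at depth `h` (default 2) of the
   negated distance map, imposed as the only regional minima by
   morphological reconstruction (the classic `imimposemin` recipe) to
   prevent over-segmentation; ridges are 4-connected and labelled 0.
6. **Area-based selection** keeps the largest region (ties go to the
   lowest label) and masks the input with it; the upper-right quadrant of
   the mask bounding box is cropped as the minor ROI and resized to
   112×112 by bilinear interpolation. 112 was chosen so the level-4
   periodized wavelet bands are 7×7 and the wavelet feature subset has
   exactly 196 entries. A manual crop box can be supplied instead of the
   automatic quadrant, standing in for the operator interaction of a
   semi-automatic workflow.

## Enhancement

Global percentile stretch (defaults (2, 98)) maps the clipped percentile
range onto [0, 255] with round-half-up; the local stretch repeats this in
a sliding window (default 15 px, edge-replicate padding); flat windows
leave pixels unchanged, and a window at least as large as the image is
special-cased to the global stretch, making the full-window limit exact.
Order is global-then-local. These algorithmic choices (formulas, window,
composition order) are package decisions; only the method family
(combined local + global stretching) is prescribed by the approach being
implemented.

## Features

* **Gabor bank**: complex kernels at orientations 0–150° in 30° steps and
  wavelengths 4√2·2ᵏ px capped at the image hypotenuse (bandwidth 1
  octave); full-image magnitude responses are Gaussian-smoothed
  (σ = 2 px) and concatenated. Dimensionality is
  `n_λ · n_θ · n_pixels`, hence the mandatory PCA downstream.
* **Wavelets**: 4-level 2-D DWT, discrete Meyer (`dmey`) basis with
  periodization. Subset 1 concatenates the level-4 bands in the fixed
  order CA‖CH‖CV‖CD. Note that `dmey` — in PyWavelets exactly as in other
  numerical environments — is a 62-tap FIR *approximation* of the Meyer
  wavelet whose filters satisfy orthogonality only to ~1e-4; multilevel
  round-trip error is therefore ~2e-3 and a constant image retains small
  nonzero details. The transform machinery itself is exact: with a
  numerically orthogonal basis (e.g. `sym8`) round-trip error is below
  1e-8 and Parseval holds to 1e-6, which is what the property tests
  assert. `dmey` remains the classification default for fidelity to the
  method being reproduced; its approximation quality is characterized by
  a separate test.
* **GLCM**: min–max quantization to G = 8 gray levels, one-pixel
  horizontal offset (0, 1), non-symmetric, normalized to sum 1. Counting
  is direct pair counting (exact for any integer offset). Descriptors:
  contrast, correlation (0 by convention when a marginal std is 0),
  energy, homogeneity ΣP/(1+|i−j|).
* **Statistics** (9 values): mean, variance (N−1), std, skewness and
  excess kurtosis standardized by the sample std (0 when σ = 0), RMS
  √(mean of squares) of the intensity sample; entropy −ΣP ln P (natural
  log, 0·ln 0 := 0) and IDM ΣP/(1+(i−j)²) of the normalized GLCM;
  smoothness 1 − 1/(1+ΣP) evaluated verbatim on the normalized matrix —
  which is identically 0.5 — retained deliberately for fidelity, with
  `glcm_smoothness=False` switching to the variance-based form
  1 − 1/(1+σ²).
* **Subsets**: 1 = wavelet bands (196); 2 = Gabor; 3 = GLCM + statistics
  of the spatial ROI (13); 4 = 1‖3 (209); 5 = GLCM + statistics of the
  level-4 coefficient grid, tiled 2×2 as [CA CH; CV CD] (13);
  6 = 2‖5. Subsets 2 and 6 must pass through PCA.

## Reduction

PCA by thin SVD of the centred training matrix; components ranked by
explained variance, sign-fixed (largest-|loading| positive). Retention:
smallest count reaching 95% cumulative variance, capped at rows−1, or a
fixed count. The fit happens inside each training fold during
cross-validation; a guard test verifies the model is sample-dependent.

## Classifiers

* **DQDA / Gaussian naive Bayes** share per-class, per-feature Gaussian
  estimates (variances floored at 1e-9 × mean feature variance); with
  identical estimates their decisions coincide, which the tests exploit
  as an independent oracle. Computation is in log space.
* **Cosine K-NN**: k = 10, distance 1 − cos, inverse-distance vote
  weights; an exact training match decides outright; vote ties break to
  the smallest class index (the global tie-break convention).
* **RBF network**: centres by seeded k-means (2 per class by default),
  Gaussian widths σ = median inter-centre distance, output weights by
  ridge least squares (λ = 1e-6) on one-hot indicators. Inputs are
  z-scored inside the model: the texture features span four orders of
  magnitude and unscaled radial distances would be dominated by the
  largest feature (empirically, chance-level accuracy). The classic RBF
  recipe leaves scaling open; this is our choice.
* **Random forest**: 100 trees, information-gain splits, bootstrap per
  tree (scikit-learn backend). Gain *ratio* is not available there;
  information gain is the closest standard criterion.
* **Bagging**: 60 size-n bootstrap resamples (redrawn if a class drops
  below 2 members, deterministically), majority vote.
* **AdaBoost.M1, resampling variant**: weight-proportional resamples,
  learner weight ln((1−ε)/ε), misclassified instances upweighted and
  renormalized; early stop at ε = 0 (the learner becomes decisive) or
  ε ≥ 0.5 (first-round fallback to the single learner).

## Evaluation

Accuracy, precision (0 with a log note when nothing is predicted
positive), sensitivity, and rank-based AUC (Mann–Whitney, ties ½).
Cross-validation: stratified 5 folds × 10 repeats, folds redrawn per
repeat from seeds derived from one master seed; all learning-from-data
preprocessing is fold-local. Segmentation is scored by Dice, Jaccard
(= D/(2−D)), specificity, sensitivity, pixel accuracy and precision.
The one-way ANOVA runs on per-repeat mean accuracies per classifier
(10 values per group) — the grouping is exposed since finer (per-fold)
grouping inflates the within-group df.

## Phantom generator

Concentric-ellipse geometry with centres/axes jittered ±10% per seed:
background 15, maternal band 120 (coarse speckle, grain 4, amplitude
0.15) touching the frame, fluid gap 35, skull ring 225 (≥3 px thick),
brain interior 140 with multiplicative speckle (smoothed unit-variance
noise; grain 2.5 px, amplitude 0.18). Abnormal phantoms overwrite the
upper-right brain quadrant with a lesion texture (grain 0.8 px, amplitude
0.30) offset by +25 intensity; the lesion uses a dedicated random stream
so a healthy/abnormal pair from one seed is bit-identical outside the
quadrant. Additive Gaussian noise (σ = 2) is applied before clipping to
8-bit. Ground truth is the filled skull outline. Defaults were chosen
once to give a clean, recoverable class signal (the GLCM contrast of the
lesion quadrant separates classes on every seed tested) — they define the
test conditions and are not calibrated to any external dataset.

What the phantom does **not** emulate: acquisition physics, partial
volume and bias fields, fetal pose variation, multi-slice anatomy, or the
heterogeneous appearance of real pathologies. Passing tests therefore
demonstrate correctness and internal consistency of the pipeline, not
clinical performance; on real data the segmentation thresholds, ROI
placement and the effect size would all be harder.

## Numerical choices and degenerate inputs

Ties everywhere break toward the smallest label/class index. Empty
foreground after any segmentation step raises an error naming the step.
Constant images: unchanged by both stretches; GLCM collapses to a single
cell with correlation 0 by convention; skewness/kurtosis are 0 when
σ = 0. Watershed depth h = 2 by default; markers falling empty (depth
exceeding every basin) degrade gracefully to the global distance maximum.
All randomness flows from explicit integer seeds; identical configuration
and seed reproduce reports byte-for-byte.

## Problem sizes

The standard test cohort is 60 phantoms (30 per class, 256² px) with
5×10 cross-validation; the segmentation benchmark uses 20 seeded
phantoms; oracle checks use 50 random 8×8 images. These sizes were chosen
as the smallest that exercise every code path with stable statistics.

## Known limitations

Single-slice 2-D only; no DICOM/NIfTI; the Gabor subsets' exact
dimensionality depends on the ROI size and wavelength ladder, so
published feature counts for those subsets are configuration-dependent;
`dmey`'s FIR approximation bounds wavelet reconstruction accuracy at
~1e-3 regardless of implementation; ensembles of random forests are
computationally redundant (a forest is already a bagged ensemble) and are
included for protocol completeness.
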