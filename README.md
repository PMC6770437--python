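# fetalbrain

Texture-based classification of fetal brain abnormalities in single-slice
T2-weighted MRI exports. Fetal MRI shows the fetal head embedded in
maternal tissue and amniotic fluid; before any diagnostic statement can be
made, the brain has to be isolated, and the abnormality signal — subtle
changes in tissue texture — has to be quantified. This package implements
a five-phase pipeline for that task, aimed at medical-imaging researchers
who need a tested, reproducible reference implementation exercisable
end-to-end on synthetic data:

1. **Segmentation** — adaptive local-mean thresholding
   (`I_binary(i,j) = 1 iff I(i,j) ≥ T(i,j)`), morphological opening and
   closing with a shared structuring element, border clearing, boundary
   tracing into a parent/child hierarchy, marker-controlled watershed on
   the distance transform (H-minima markers, imposed minima), and
   largest-area selection. The result is the whole-brain image and an
   upper-right "minor ROI" where the abnormality signal concentrates.
2. **Enhancement** — combined global + local percentile contrast
   stretching of the minor ROI.
3. **Feature extraction** — a Gabor filter bank (orientations 0–150° in
   30° steps, wavelengths 4√2 px doubling up to the image hypotenuse),
   a 4-level 2-D discrete Meyer wavelet transform (periodized), gray-level
   co-occurrence descriptors (contrast, correlation Σᵢⱼ ij·P(i,j) − μxμy /
   σxσy, energy ΣP², homogeneity ΣP/(1+|i−j|)) and statistical moments
   (mean, variance with N−1, std, skewness, excess kurtosis, entropy
   −ΣP log P, inverse difference moment, RMS, smoothness), assembled into
   six feature subsets.
4. **Reduction** — PCA of the high-dimensional Gabor subsets (2 and 6),
   always fit fold-locally.
5. **Classification** — diagonal QDA (δₖ(x) = −½log|Σₖ| −
   ½(x−μₖ)ᵀΣₖ⁻¹(x−μₖ) + log πₖ with diagonal Σₖ), Gaussian naive Bayes,
   cosine K-NN (k=10, inverse-distance weights), an RBF network and a
   random forest, plus bagging and AdaBoost.M1 ensembles (60 learners),
   evaluated by stratified 5-fold cross-validation repeated 10 times
   (accuracy, precision, sensitivity, rank-based AUC) with a one-way
   ANOVA across models.

A seeded **phantom generator** produces fetal-head-like slices (maternal
band, fluid gap, bright skull ellipse, speckle-textured brain, optional
upper-right lesion) with ground-truth masks and labels, so every stage is
testable without clinical data.

## Worked example

```bash
python examples/02_segment_brain.py
```

```
Dice vs ground truth: 1.000  (Jaccard 1.000, sensitivity 1.000)
minor ROI box (row, col, h, w): (59, 133, 69, 64), resized to (112, 112)
  after binary    :  27630 foreground px
  after open      :  26800 foreground px
  after clear     :  12587 foreground px
  after close     :  12697 foreground px
  after region    :  19384 foreground px
  after abs       :  14001 foreground px
```

A Dice of 1.0 means the watershed's largest basin coincides exactly with
the phantom's skull-enclosed brain; the per-step counts show the border
clearing removing the maternal band (~14k px) and the boundary-tracing /
region step recovering the filled brain candidate. The other examples
cover phantom generation, the six feature subsets (subsets 3 and 5 print
their 13 named descriptors), PCA of the Gabor responses, and cohort
classification:

```bash
python examples/05_classify_cohort.py
```

```
single-knn   accuracy 1.000 +- 0.000   AUC 1.000
single-nb    accuracy 1.000 +- 0.000   AUC 1.000
bag-nb       accuracy 1.000 +- 0.000   AUC 1.000
boost-nb     accuracy 1.000 +- 0.000   AUC 1.000

ANOVA across models: F = 0.00, p = 1
```

At the phantom's default lesion effect size the task is cleanly
separable, so all models agree and the ANOVA finds no difference.

## Command line

```bash
fetalbrain phantom --n-per-class 30 --seed 7 --out cohort/
fetalbrain segment cohort/img_0000.png --out seg/
fetalbrain run --input cohort/ --out results/ --subset 3 --model knn
```

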