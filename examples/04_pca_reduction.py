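"""Reduce the high-dimensional Gabor subset with PCA.

The Gabor bank emits one smoothed magnitude image per
(wavelength, orientation) pair, so the vector is tens of thousands of
dimensions for a handful of samples; PCA keeps the directions that carry
the configured fraction of variance.
"""

import numpy as np

from fetalbrain import (FeatureConfig, GaborBankSpec, PhantomSpec,
                        assemble_subset, enhance_roi, generate_cohort,
                        pca_fit, pca_transform, segment_brain)

cohort = generate_cohort(PhantomSpec(seed=3, image_size=128), n_per_class=5)
cfg = FeatureConfig(gabor=GaborBankSpec(wavelengths=(8.0, 16.0)))
X = np.vstack([assemble_subset(
    enhance_roi(segment_brain(item.image).minor_roi), 2, cfg)[0]
    for item in cohort])

model = pca_fit(X, variance_fraction=0.95)
Z = pca_transform(model, X)
explained = model.explained_variance / model.explained_variance.sum()
print(f"input: {X.shape[0]} samples x {X.shape[1]} Gabor features")
print(f"retained {model.n_components} components "
      f"({Z.shape[1]} columns) for 95% of variance")
print("per-component variance share:",
      np.round(explained[: model.n_components], 3))
# With 10 samples at most 9 directions exist; the leading few usually
# absorb nearly all texture variance, which is why subsets 2 and 6 are
# always reduced before classification.
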