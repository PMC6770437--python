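"""Extract the six texture feature subsets from an enhanced minor ROI.

Subsets 3 and 5 are the 13 named co-occurrence + statistical descriptors
(spatial domain and level-4 wavelet domain); subset 1 is the 196 level-4
wavelet coefficients; subsets 2 and 6 are the high-dimensional Gabor
responses destined for PCA.
"""

from fetalbrain import (FeatureConfig, GaborBankSpec, PhantomSpec,
                        assemble_subset, enhance_roi, generate_phantom,
                        segment_brain)

phantom = generate_phantom(PhantomSpec(seed=1), "abnormal")
roi = enhance_roi(segment_brain(phantom.image).minor_roi)

cfg = FeatureConfig(gabor=GaborBankSpec(wavelengths=(8.0, 16.0)))
for sid in range(1, 7):
    vec, names = assemble_subset(roi, sid, cfg)
    print(f"subset {sid}: {vec.size:7d} features "
          f"(first: {names[0]} = {vec[0]:.4f})")

vec3, names3 = assemble_subset(roi, 3, cfg)
print("\nsubset 3 descriptors of the lesion-bearing ROI:")
for n, v in zip(names3, vec3):
    print(f"  {n:22s} {v:12.4f}")
# contrast/correlation/energy/homogeneity summarize the co-occurrence
# matrix; the remaining nine are moments and information measures of the
# intensity sample and the same matrix.
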