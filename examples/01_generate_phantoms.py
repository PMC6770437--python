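"""Generate a seeded synthetic cohort and inspect its ground truth.

The phantom emulates a single T2-like fetal head slice: maternal tissue
touching the frame, a dark fluid gap, a bright skull ellipse and a
speckle-textured brain.  Abnormal phantoms add a lesion confined to the
upper-right quadrant of the brain.
"""

import numpy as np

from fetalbrain import PhantomSpec, generate_cohort, generate_phantom
from fetalbrain.phantom import lesion_box

spec = PhantomSpec(seed=1)
healthy = generate_phantom(spec, "healthy")
abnormal = generate_phantom(spec, "abnormal")

print(f"image: {healthy.image.shape[0]}x{healthy.image.shape[1]} uint8, "
      f"brain mask covers {healthy.brain_mask.mean():.1%} of the frame")
diff = np.flatnonzero(healthy.image != abnormal.image).size
print(f"healthy vs abnormal (same seed): {diff} px differ, "
      f"all inside the lesion box {lesion_box(healthy.brain_mask)}")

cohort = generate_cohort(PhantomSpec(seed=7), n_per_class=5)
labels = [item.label for item in cohort]
print(f"cohort: {len(cohort)} phantoms, "
      f"{labels.count('healthy')} healthy / {labels.count('abnormal')} abnormal")
# The per-class balance mirrors a case/control study; the lesion contrast
# and speckle grain are the knobs that set the difficulty of the task.
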