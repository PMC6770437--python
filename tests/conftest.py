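"""Shared fixtures: seeded phantoms and the 60-image evaluation cohort."""

import numpy as np
import pytest

from fetalbrain import (PhantomSpec, enhance_roi, feature_matrix,
                        generate_cohort, generate_phantom, segment_brain)


@pytest.fixture(scope="session")
def healthy_phantom():
    return generate_phantom(PhantomSpec(seed=1), "healthy")


@pytest.fixture(scope="session")
def abnormal_phantom():
    return generate_phantom(PhantomSpec(seed=1), "abnormal")


@pytest.fixture(scope="session")
def cohort60():
    """The default study cohort: 30 healthy + 30 abnormal phantoms, seed 7."""
    return generate_cohort(PhantomSpec(seed=7), 30)


@pytest.fixture(scope="session")
def cohort60_subset3(cohort60):
    """Segment + enhance every cohort image; subset-3 features and labels."""
    rois = [enhance_roi(segment_brain(item.image).minor_roi)
            for item in cohort60]
    X = feature_matrix(rois, 3).to_numpy()
    y = np.array([0 if item.label == "healthy" else 1 for item in cohort60])
    return X, y
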