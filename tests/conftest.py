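import numpy as np
import pytest

from fcnets import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three subjects, 24 ROIs in three planted communities, stationary coupling."""
    spec = CohortSpec(n_subjects=3, n_rois=24, n_timepoints=160,
                      community_sizes=(10, 8, 6), seed=42)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
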