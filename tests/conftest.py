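import numpy as np
import pytest

from crcmeta.io import CohortProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_profile(rng):
    """A 20-feature, 12-sample cohort with valid compositional columns."""
    raw = rng.gamma(0.5, size=(20, 12))
    ab = raw / raw.sum(axis=0, keepdims=True)
    return CohortProfile(
        cohort_id="test_cohort",
        feature_ids=[f"SGB{i:04d}" for i in range(20)],
        sample_ids=[f"s{j:02d}" for j in range(12)],
        abundances=ab,
    )
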