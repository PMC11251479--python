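import numpy as np
import pytest

from psdconn.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small deterministic cohort shared across read-only tests."""
    spec = CohortSpec(n_per_group={"HC": 4, "Stroke": 4, "PSD": 4},
                      grid_shape=(10, 10, 8), n_timepoints=80,
                      lesion_size_range=(8, 20), rng_seed=42)
    subjects, records, truth = generate_cohort(spec)
    return spec, subjects, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
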