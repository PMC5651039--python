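import numpy as np
import pytest

from ppikit import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-subject default-parameter two-run cohort, shared across tests."""
    return generate_cohort(CohortSpec(n_subjects=10, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
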