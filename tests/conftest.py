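import numpy as np
import pytest

from lbsiz.pipeline import score_cohort
from lbsiz.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate default-parameter cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n=4000, seed=20260922))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    return score_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
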