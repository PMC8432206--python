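import numpy as np
import pytest

from sgascreen import REFERENCE_RATIO, REFERENCE_SFLT1, PriorParams
from sgascreen.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def ratio_params():
    return REFERENCE_RATIO


@pytest.fixture(scope="session")
def sflt1_params():
    return REFERENCE_SFLT1


@pytest.fixture(scope="session")
def simple_prior():
    """Independent outcome prior: GA ~ N(39.5, 2) on [24, 43], Z ~ N(0, 1)."""
    return PriorParams.independent()


@pytest.fixture(scope="session")
def small_cohort():
    """A 3000-pregnancy default-configuration cohort, generated once."""
    return generate_cohort(CohortConfig(n_pregnancies=3000, seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """One full-scale (n = 40241) default cohort, generated once per run."""
    return generate_cohort(CohortConfig(n_pregnancies=40241, seed=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
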