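import numpy as np
import pytest

from mtdrive.biomarkers import prepare_biomarkers
from mtdrive.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_small():
    """Default-calibrated cohort, small enough for fast unit tests."""
    return generate_cohort(CohortConfig(n=2000), seed=11)


@pytest.fixture(scope="session")
def cohort_large():
    """Cohort sized for Monte-Carlo calibration checks."""
    return generate_cohort(CohortConfig(n=10000), seed=7)


@pytest.fixture(scope="session")
def prepared_small(cohort_small):
    cu = (cohort_small["diagnosis"] == "CU").to_numpy()
    return prepare_biomarkers(cohort_small, cu), cu


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
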