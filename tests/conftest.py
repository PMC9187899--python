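import numpy as np
import pandas as pd
import pytest

from sepsis_phenoscope import preprocess
from sepsis_phenoscope.synthetic_cohort import CohortConfig, sample_cohort


@pytest.fixture(scope="session")
def cohort():
    """A complete-case default cohort (no injected missingness)."""
    return sample_cohort(CohortConfig(n_patients=2371, missing_rate=0.0, seed=11))


@pytest.fixture(scope="session")
def cohort_normalized(cohort):
    norm = preprocess.fit_normalizer(cohort)
    return preprocess.apply_normalizer(norm, cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
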