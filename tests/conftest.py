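import warnings

import numpy as np
import pytest

from habitatrad import synthetic_cohort as sc
from habitatrad import habitat_partition as hp

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient cohort at generator defaults; shared across tests."""
    return sc.generate_cohort(sc.CohortSpec(n_patients=12, seed=3))


@pytest.fixture(scope="session")
def t1w_partition(small_cohort):
    """T1W partition of the shared cohort (model, partitions, entropy maps)."""
    model, parts, ems = hp.partition_sequence(
        small_cohort, "T1W", seed=0, fit_splits=("train", "internal", "external")
    )
    return model, parts, ems


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
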