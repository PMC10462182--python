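import numpy as np
import pytest

from regcal import CohortDefinition, lss_cohort


@pytest.fixture(scope="session")
def cohort():
    return lss_cohort()


@pytest.fixture
def tiny_cohort():
    """Small two-group cohort for cheap exact checks."""
    return CohortDefinition(group_ids=(1, 2), central_doses=(0.5, 2.0),
                            n_persons=(40, 10))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
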