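import numpy as np
import pytest

from schemasim import cohort as coh
from schemasim import design as dsg


@pytest.fixture(scope="session")
def default_lists():
    return dsg.make_stimulus_lists(seed=123)


@pytest.fixture(scope="session")
def short_list(default_lists):
    return default_lists[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    cfg = coh.CohortConfig(n_participants=4, rois={"mpfc": 60})
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return coh.simulate_cohort(small_config, seed=7)
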