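import numpy as np
import pytest
from hypothesis import settings

from heelpad.config import paper_defaults
from heelpad.synthetic import sample_cohort, simulate_stance

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def default_cfg():
    return paper_defaults()


@pytest.fixture
def noiseless_cfg():
    cfg = paper_defaults()
    cfg.cohort.noise_cv = 0.0
    return cfg


@pytest.fixture
def noiseless_heel(noiseless_cfg):
    """One heel's ground-truth parameters with measurement noise off."""
    return sample_cohort(noiseless_cfg.cohort, seed=1)[0]


@pytest.fixture
def noiseless_trial(noiseless_cfg, noiseless_heel):
    return simulate_stance(noiseless_heel, noiseless_cfg.gait, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
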