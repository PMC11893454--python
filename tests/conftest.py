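import numpy as np
import pytest

from linklab.params import ModelParams
from linklab.protocol import ExperimentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A reduced network for fast protocol-level unit tests."""
    return ModelParams(
        n_exc_l1=20,
        n_exc_l2=20,
        n_branches=4,
        n_bg_syn_per_branch=3,
        n_mem_sources=10,
        n_mem_contacts=40,
        n_soma_inter=5,
        n_dend_inter=5,
    )


@pytest.fixture
def small_cfg():
    return ExperimentConfig(interval="5h", n_trials=1, seed=0)
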