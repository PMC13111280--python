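import numpy as np
import pytest

from asym.config import load_config
from asym.ssm_core import BiMambaConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """A small Bi-Mamba config for fast unit tests."""
    return BiMambaConfig(model_width=8, state_dim=4, conv_kernel=4,
                         expansion=1.0, n_blocks=1)


@pytest.fixture
def synth_run_config():
    """Small-model run config for end-to-end tests."""
    return load_config(profile="synth", overrides={
        "synthetic.n_per_class": 10,
        "synthetic.t_range": [64, 64],
        "synthetic.f_audio": 5,
        "synthetic.f_video": 7,
        "seed": 7,
    })


@pytest.fixture
def small_pairs(synth_run_config):
    from asym.data_io import generate_synthetic
    return generate_synthetic(synth_run_config.synthetic_spec())
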