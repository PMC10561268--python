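import numpy as np
import pytest

from hpcnet.config import NetworkConfig
from hpcnet.core import init_weights, reset_state


@pytest.fixture
def tiny_config():
    """A 3-area network small enough for brute-force oracles."""
    return NetworkConfig(
        area_sizes=(6, 4, 3),
        inference_rate=0.05,
        learning_rate=0.01,
        activation_offset=-1.0,
        inference_steps_per_cycle=10,
        cycles_per_frame=3,
        reset_rate=0.1,
        seed=7,
        convergence_tol=1e-6,
        max_convergence_steps=500,
    )


@pytest.fixture
def tiny_weights(tiny_config):
    return init_weights(tiny_config, seed=tiny_config.seed)


@pytest.fixture
def tiny_state(tiny_config):
    return reset_state(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
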