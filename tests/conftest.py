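import numpy as np
import pytest

from dcflow.presets import (oscillator_data_config, oscillator_model_config,
                            oscillator_train_config)
from dcflow.synthetic_data import make_constant_shift, make_embedded_oscillator
from dcflow.training import train


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def osc_dataset():
    """Planar rotation in D=20 ambient dimensions, mild noise."""
    return make_embedded_oscillator(oscillator_data_config())


@pytest.fixture(scope="session")
def shift_dataset():
    w = np.zeros(5)
    w[:2] = (0.15, -0.1)
    return make_constant_shift(5, w, n_traj=10, n_steps=20, seed=3)


def _train_osc(dataset, seed):
    state, log = train(dataset, oscillator_train_config(seed=seed),
                       oscillator_model_config())
    return state, log


@pytest.fixture(scope="session")
def osc_run_a(osc_dataset):
    return _train_osc(osc_dataset, seed=0)


@pytest.fixture(scope="session")
def osc_run_b(osc_dataset):
    return _train_osc(osc_dataset, seed=1)
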