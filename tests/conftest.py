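import numpy as np
import pytest

from microsleepnet import ModelConfig, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return ModelConfig()


@pytest.fixture
def tiny_config():
    """A narrow variant for fast training-path tests."""
    return ModelConfig(width_multiplier_alpha=0.25)


@pytest.fixture
def synth_config():
    return SyntheticConfig()


def numeric_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at selected points of x."""
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        ij = it.multi_index
        xp = x.copy()
        xp[ij] += eps
        xm = x.copy()
        xm[ij] -= eps
        grad[ij] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return grad
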