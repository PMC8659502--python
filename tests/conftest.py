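import numpy as np
import pytest

from ocnmf import FactorizationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spectrogram(rng):
    """A small random non-negative matrix standing in for a magnitude."""
    return rng.random((24, 40)) * 2.0


@pytest.fixture
def tiny_cfg():
    """A configuration small enough for sub-second fits."""
    return FactorizationConfig(
        R=5, J=3, K=3, beta=2.0, mu=1.0e4, iters_train=40, iters_analysis=40, seed=7
    )
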