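import numpy as np
import pytest

from flif.params import ModelParams, TimeGrid, table1_params


@pytest.fixture(scope="session")
def table1() -> ModelParams:
    """Standard parameter set (tau_m = 20 ms, rheobase 0.5 nA)."""
    return table1_params()


@pytest.fixture
def short_grid() -> TimeGrid:
    return TimeGrid(dt=0.1, n_steps=1000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
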