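import numpy as np
import pytest

from ticsim import TIParams, find_v_crit


@pytest.fixture(scope="session")
def default_params() -> TIParams:
    return TIParams()


@pytest.fixture(scope="session")
def crit(default_params):
    """Saddle-node location for the default circuit (computed once)."""
    return find_v_crit(default_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
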