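import numpy as np
import pytest

from pomcon import M1_PARAMS, ModelParams


@pytest.fixture
def m1() -> ModelParams:
    return M1_PARAMS


@pytest.fixture
def toy_params() -> ModelParams:
    """Small, fast parameter set used for policy/oracle comparisons."""
    return ModelParams(w_z=1.0, sigma_z=2.0, sigma_0=1.0, cost=1e-3, horizon=10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
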