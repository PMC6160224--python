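import numpy as np
import pytest

from beemb import BeeModel, ModelParams


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams().calibrated()


@pytest.fixture(scope="session")
def unit_params() -> ModelParams:
    """Parameters with gain 1 so layer arithmetic is directly inspectable."""
    return ModelParams(kc_gain=1.0)


@pytest.fixture()
def bee(params) -> BeeModel:
    return BeeModel(params, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
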