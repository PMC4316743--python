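import numpy as np
import pytest
from hypothesis import settings

from pemotor import ModelParams, PrimitivePopulation

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def best_params() -> ModelParams:
    """The default (best-fit) parameter set used throughout the simulations."""
    return ModelParams.best_fit()


@pytest.fixture(scope="session")
def grid_pop(best_params) -> PrimitivePopulation:
    return PrimitivePopulation.grid(best_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
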