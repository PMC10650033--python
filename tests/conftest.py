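import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from intrares import ModelParams, StageDistribution

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def params() -> ModelParams:
    return ModelParams.default()


@pytest.fixture
def stages() -> StageDistribution:
    return StageDistribution()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
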