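import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from bgopto import LearningParams, ModelState, PolicyParams, TaskConfig  # noqa: E402


@pytest.fixture
def lp() -> LearningParams:
    return LearningParams()


@pytest.fixture
def pp() -> PolicyParams:
    return PolicyParams(eligible_actions=(0, 1))


@pytest.fixture
def fresh_model() -> ModelState:
    return ModelState.initial(5, 4)


@pytest.fixture
def two_action_task() -> TaskConfig:
    return TaskConfig(
        n_states=1, n_actions=2, left_action=0, right_action=1,
        recorded_state=0, n_blocks=50,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
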