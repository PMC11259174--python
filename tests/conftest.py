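import numpy as np
import pytest

from fireflynav.task_env import TaskConfig


@pytest.fixture
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture
def noise_free_config() -> TaskConfig:
    return TaskConfig(alpha_a=0.0, alpha_o=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


class ForcedUniform:
    """rng stub returning scripted values from successive uniform() calls."""

    def __init__(self, values):
        self._values = list(values)

    def uniform(self, lo, hi):
        return self._values.pop(0)


@pytest.fixture
def forced_uniform():
    return ForcedUniform
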