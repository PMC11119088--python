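import numpy as np
import pytest

from flankit.engine import run_session
from flankit.enums import Condition, Response
from flankit.schedule import TaskConfig
from flankit.staircase import StaircaseConfig


@pytest.fixture
def traditional_config():
    return TaskConfig(condition=Condition.TRADITIONAL)


@pytest.fixture
def gamified_config():
    return TaskConfig(condition=Condition.GAMIFIED, staircase=StaircaseConfig())


@pytest.fixture
def perfect_responder():
    """Always presses the target direction, quickly."""

    def responder(spec, window_ms, rng):
        return Response(spec.target_direction.value), min(400.0, window_ms)

    return responder


@pytest.fixture
def absent_responder():
    """Never responds."""

    def responder(spec, window_ms, rng):
        return Response.NONE, None

    return responder


@pytest.fixture
def rng():
    return np.random.default_rng(20240451)
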