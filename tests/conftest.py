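import numpy as np
import pytest
from hypothesis import settings

from lv05abc import LV05Config, ParticipantParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def config():
    """Default model constants with a small Monte-Carlo budget."""
    return LV05Config(n_trials=2000)


@pytest.fixture
def reference_participant():
    return ParticipantParams(LF=0.2, CW=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
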