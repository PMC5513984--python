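import numpy as np
import pytest

from wrrc.audio import make_word_list, synth_babble, synth_beat, synth_word_token
from wrrc.stimulus import ConditionSpec, build_timeline


@pytest.fixture(scope="session")
def word_list():
    """One default 16-word list (44.1 kHz)."""
    return make_word_list(seed=42)


@pytest.fixture(scope="session")
def token():
    return synth_word_token(0.300, 1, seed=7)


@pytest.fixture(scope="session")
def beat():
    return synth_beat()


@pytest.fixture(scope="session")
def babble_5s():
    return synth_babble(5.0, 8, seed=3)


@pytest.fixture(scope="session")
def rh_timeline(token):
    return build_timeline(token, ConditionSpec("RH"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
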