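import numpy as np
import pytest

from rpdsim import StageGame, make_named_strategy


@pytest.fixture(scope="session")
def game():
    """The reference prisoner's dilemma: R,S,T,P = 3,0,4,1 with delta = 0.75."""
    return StageGame(R=3.0, S=0.0, T=4.0, P=1.0, delta=0.75)


@pytest.fixture(scope="session")
def named():
    return {
        name: make_named_strategy(name)
        for name in ("ALLC", "ALLD", "TFT", "GRIM", "STFT", "CTFT", "WSLS")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20180829)
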