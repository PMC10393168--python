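import numpy as np
import pytest

from coopmove import GameParams, MovementParams, build_network


@pytest.fixture(scope="session")
def complete2():
    return build_network("complete", 2)


@pytest.fixture(scope="session")
def complete4():
    return build_network("complete", 4)


@pytest.fixture(scope="session")
def complete10():
    return build_network("complete", 10)


@pytest.fixture(scope="session")
def circle10():
    return build_network("circle", 10)


@pytest.fixture(scope="session")
def star5():
    return build_network("star", 5)


@pytest.fixture
def default_move():
    """Study-condition movement parameters: S=0.03, +1/-1, T=10."""
    return MovementParams()


@pytest.fixture
def default_game():
    """Study-condition game parameters: v=0.4, c=0.04."""
    return GameParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
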