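import numpy as np
import pytest

from limres import GameParams, LatticeState


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params():
    return GameParams(L=4, b=1.5, c=1.1)


def random_state(L: int, seed: int) -> LatticeState:
    return LatticeState(cp=np.random.default_rng(seed).random((L, L)))


def homogeneous_state(L: int, p: float) -> LatticeState:
    return LatticeState(cp=np.full((L, L), p))
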