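import numpy as np
import pytest
from hypothesis import settings

from minforage import env
from minforage.markov_brain import encode_gate

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def q_world():
    return env.build_world("Q", seed=7)


@pytest.fixture
def ga_world():
    return env.build_world("GA", seed=7)


def greedy_forager_genome() -> list[int]:
    """Hand-wired deterministic brain: step FORWARD when the tile ahead is
    food, otherwise turn RIGHT.

    One gate reading the two front-code sensor bits (nodes 0 high, 1 low)
    into the two movement actuators (nodes 16 high-bit-first in the output
    wiring below).  Input pattern index has node 0 as bit 0, node 1 as bit
    1; food ahead is code 01 (hi=0, lo=1) -> pattern 2.  Output pattern bit
    0 drives node 16 (movement high bit), bit 1 drives node 17: FORWARD
    (code 11) is pattern 3, RIGHT (code 10) is pattern 1.
    """
    return encode_gate(inputs=[0, 1], outputs=[16, 17], table=[1, 1, 3, 1])


@pytest.fixture
def forager_genome():
    return greedy_forager_genome()
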