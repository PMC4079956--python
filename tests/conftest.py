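import numpy as np
import pytest

from urimir import synth


@pytest.fixture(scope="session")
def demo_world():
    """Small reproducible reference tiers + auxiliary databases."""
    return synth.make_demo_references(seed=11)


@pytest.fixture(scope="session")
def tiers(demo_world):
    return demo_world[0]


@pytest.fixture(scope="session")
def dbs(demo_world):
    return demo_world[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
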