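import numpy as np
import pytest

from spiralfold import Conformation, generate_random_instance, random_saw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def corner_4mer():
    """4-mer whose only nonconsecutive unit-distance pair is (0, 3)."""
    return [(0, 0, 0), (1, 1, 0), (2, 0, 0), (1, -1, 0)]


def random_conformation(n: int, seed: int, h_fraction: float = 0.5) -> Conformation:
    """Random HP instance on a random SAW (shared test helper)."""
    rng = np.random.default_rng(seed)
    seq = generate_random_instance(n, h_fraction, rng)
    return Conformation(seq, random_saw(n, rng))
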