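import numpy as np
import pytest

from piwe import Sequence

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int, name: str = "s") -> Sequence:
    return Sequence(name, "".join(rng.choice(list(BASES), size=length)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequences(rng):
    """30 random sequences of piRNA-like lengths."""
    return [
        random_sequence(rng, int(rng.integers(16, 36)), f"s{i}") for i in range(30)
    ]
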