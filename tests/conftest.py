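import numpy as np
import pytest


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_dna(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    """Random sequence over ACGT, optionally salted with N positions."""
    probs = [(1 - n_prob) / 4] * 4 + [n_prob]
    return "".join(rng.choice(list("ACGTN"), size=length, p=probs))
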