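import numpy as np
import pytest

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_929)
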