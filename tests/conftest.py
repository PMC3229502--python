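import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_dna(rng, n, gc=0.5):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bases[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")
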