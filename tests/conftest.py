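import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20100423)


def random_dna(rng, n: int, gc: float = 0.42) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(bases, size=n, p=p).tobytes().decode("ascii")
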