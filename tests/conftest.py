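import numpy as np
import pytest

from casforge.core_io import rng

BASES = "ACGT"


def random_dna(seed: int, n: int, stream: str = "test") -> str:
    g = rng(seed, stream)
    return "".join(BASES[c] for c in g.integers(0, 4, n))


@pytest.fixture
def mutate():
    """Substitute a base at given positions (cycled to a different base)."""

    def _mutate(seq: str, positions) -> str:
        out = list(seq)
        for p in positions:
            out[p] = BASES[(BASES.index(out[p]) + 1) % 4]
        return "".join(out)

    return _mutate
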