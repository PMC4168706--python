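import numpy as np
import pytest

from cascomp.containers import revcomp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def all_windows(genome: str, l_read: int) -> set:
    """Valid read-length windows of both strands (enumeration oracle)."""
    out = set()
    for strand in (genome, revcomp(genome)):
        for i in range(len(strand) - l_read + 1):
            w = strand[i : i + l_read]
            if set(w) <= set("ACGT"):
                out.add(w)
    return out
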