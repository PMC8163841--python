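import numpy as np
import pytest

from nucposlab import GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    return GenomeSequence(
        {
            "t1": "ACGT" * 500,  # 2000 bp
            "t2": "AAAAAATTTTTTGGGGCCCC" * 100,  # 2000 bp
        }
    )


def random_sequence(rng, length, p_gc=0.4):
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@pytest.fixture
def random_seq_factory(rng):
    return lambda length, p_gc=0.4: random_sequence(rng, length, p_gc)
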