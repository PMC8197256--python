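import numpy as np
import pytest

from kmerbind.seqrep import DNASequence
from kmerbind.simulate import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """60 bp sequences, 30 positives at ratio 1 — fast end-to-end material."""
    dataset, truth = generate_dataset(SimConfig(n_pos=30, ratio=1, seq_length=60, seed=7))
    return dataset, truth


@pytest.fixture
def random_sequences(rng):
    def make(n, length):
        return [
            DNASequence(f"s{i}", "".join(rng.choice(list("ACGT"), size=length)))
            for i in range(n)
        ]

    return make
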