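import numpy as np
import pytest

import exotsrna as x


@pytest.fixture(scope="session")
def refs():
    return x.make_toy_references(seed=42)


@pytest.fixture(scope="session")
def class_indexes(refs):
    indexes, boundaries = x.build_class_indexes(
        refs.refset, {cls: seqs for cls, seqs in refs.decoys.items()}
    )
    return indexes, boundaries


@pytest.fixture
def cparams():
    return x.ClassifierParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_read(seq: str, q: int = 30, read_id: str = "r1") -> x.RawRead:
    return x.RawRead(read_id, seq, np.full(len(seq), q, dtype=np.int16))


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
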