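import numpy as np
import pytest

from icrbp import EncodingConfig, SyntheticSpec, generate_dataset, train_doc2vec
from icrbp.sequence_io import NucleotideSequence


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticSpec(n_per_class=30, length=40, seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_encoding():
    return EncodingConfig(doc2vec_dim=8, doc2vec_epochs=2, doc2vec_min_count=2,
                          seed=3)


@pytest.fixture(scope="session")
def tiny_embedding(tiny_dataset, tiny_encoding):
    return train_doc2vec(tiny_dataset.sequences, tiny_encoding)


def random_sequence(rng: np.random.Generator, length: int, alphabet="ACGT",
                    seq_id="r") -> NucleotideSequence:
    return NucleotideSequence(
        seq_id, "".join(rng.choice(list(alphabet), size=length))
    )
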