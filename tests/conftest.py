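import numpy as np
import pytest

from gor4 import GeneratorConfig, InformationTables, generate_dataset, train


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_tables(rng):
    """Factory for random finite information tables."""

    def make(scale: float = 1.0) -> InformationTables:
        return InformationTables(
            scale * rng.normal(size=(3, 17, 21)),
            scale * rng.normal(size=(3, 136, 21, 21)),
        )

    return make


@pytest.fixture(scope="session")
def small_dataset():
    """A small but trainable synthetic dataset (fixed conditions)."""
    return generate_dataset(GeneratorConfig(n_sequences=30, mean_length=120, seed=7))


@pytest.fixture(scope="session")
def small_tables(small_dataset):
    return train(small_dataset)


TINY_DB = """>r1
ACDEFGHIKLMNPQRSTVWY
HHHHHHHHEEEECCCCCCCC
>r2
WYACDEGGG
CCCHHHHEE
>r3
MKV
CCC
"""


@pytest.fixture
def tiny_db_path(tmp_path):
    p = tmp_path / "tiny.db"
    p.write_text(TINY_DB)
    return p
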