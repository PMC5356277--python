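import numpy as np
import pytest

from rfclone import CloningJob, Config, NucSeq
from rfclone.fixtures import generate_fixture


@pytest.fixture
def toy_vector() -> NucSeq:
    # 20-bp circular vector: backbone AAAAA, overhang-A region TTTTT,
    # stuffer CCCCC (positions 11-15), overhang-B region GGGGG
    return NucSeq("toyvec", "AAAAATTTTTCCCCCGGGGG", "circular")


@pytest.fixture
def toy_insert() -> NucSeq:
    return NucSeq("toyins", "AACGT", "linear")


@pytest.fixture
def toy_job(toy_vector, toy_insert) -> CloningJob:
    return CloningJob(
        vector=toy_vector, insert=toy_insert, junction_a=10, junction_b=16,
        k=5, relax_k=True,
    )


@pytest.fixture
def toy_config() -> Config:
    return Config(k=5, relax_k=True, body_target=5, body_window=(5, 5), min_core=5)


@pytest.fixture
def small_fixture():
    return generate_fixture(seed=11, vector_len=3000, insert_len=600, k=6)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
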