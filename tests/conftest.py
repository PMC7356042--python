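import numpy as np
import pytest

from lipscout import cps1
from lipscout.proteins import ProteinRecord


@pytest.fixture(scope="session")
def cps1_record() -> ProteinRecord:
    return cps1.CPS1


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(20260922))


def random_protein(rng: np.random.Generator, length: int,
                   protein_id: str = "RND") -> ProteinRecord:
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = "".join(rng.choice(alphabet, size=length))
    return ProteinRecord(id=protein_id, sequence=seq)
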