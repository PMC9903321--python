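import random

import pytest

from qcatdesign.digest import tryptic_limit_digest
from qcatdesign.records import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: random.Random, lo: int = 50, hi: int = 500) -> str:
    return "".join(rng.choice(AA20) for _ in range(rng.randint(lo, hi)))


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord("P1", "MAKRPGKELRTTT")


@pytest.fixture
def toy_peptides(toy_protein):
    return tryptic_limit_digest(toy_protein)


@pytest.fixture
def small_proteome():
    """Deterministic 12-protein proteome for repeat searches."""
    rng = random.Random(424242)
    return [
        ProteinRecord(f"Q{i:03d}", random_sequence(rng, 80, 200))
        for i in range(12)
    ]
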