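import random

import pytest

from cysrep.seqio import ProteinRecord

#: C-heavy alphabet so random sequences actually contain repeat-core-like windows
CRICH_ALPHABET = "CCCDPQKSTVX"


@pytest.fixture
def random_crich_seq():
    """Factory for seeded cysteine-rich random sequences."""

    def make(seed: int, length: int) -> str:
        r = random.Random(seed)
        return "".join(r.choice(CRICH_ALPHABET) for _ in range(length))

    return make


@pytest.fixture
def toy_records():
    return [
        ProteinRecord(id="a", seq="CCDPCQKPCCDPCQQSV", species="toy bird"),
        ProteinRecord(id="b", seq="MWYCCDPCQTCCDPCQS"),
    ]
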