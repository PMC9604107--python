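import numpy as np
import pytest
from hypothesis import settings

from ntmap import ReferenceDB, SequenceRecord
from ntmap.align import DEFAULT_SCHEME

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(20_2210)


@pytest.fixture
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture
def small_db(rng):
    """A two-contig genome database of ~3 kb total."""
    recs = [
        SequenceRecord(id="ctgA", seq=random_seq(rng, 2000)),
        SequenceRecord(id="ctgB", seq=random_seq(rng, 1000)),
    ]
    return ReferenceDB(recs, role="genome")
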