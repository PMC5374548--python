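import random
import string

import pytest

from pairqc.fastq_io import PHRED_OFFSET, SequenceRead


def make_read(bases: str, qual: int = 35, name: str = "r") -> SequenceRead:
    return SequenceRead(name=name, bases=bases,
                        quals=chr(qual + PHRED_OFFSET) * len(bases))


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def random_reads(rng):
    def _make(n: int, length: int, qual: int = 35):
        return [make_read("".join(rng.choice("ACGT") for _ in range(length)),
                          qual=qual, name=f"r{i}")
                for i in range(n)]

    return _make
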