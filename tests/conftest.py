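import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from readaudit.fixtures import make_paper_synthetic
from readaudit.io_formats import SequenceRead

BASES = "ACGT"


@pytest.fixture(scope="session")
def paper_fixture():
    """The 10-chromosome / 1,000-read synthetic validation dataset."""
    scaffolds, reads, truth = make_paper_synthetic(seed=42)
    return scaffolds, reads, truth


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_read_set(
    rng: np.random.Generator,
    n_reads: int,
    length_range: tuple[int, int] = (5, 40),
) -> list[str]:
    """A read set with organic duplicates and containments.

    Roughly half the reads are fresh random strings; the rest are copies or
    substrings of earlier reads, so identical and inclusive redundancy both
    occur naturally.
    """
    lo, hi = length_range
    reads: list[str] = []
    for _ in range(n_reads):
        mode = rng.random()
        if not reads or mode < 0.5:
            reads.append(random_sequence(rng, int(rng.integers(lo, hi + 1))))
        elif mode < 0.75:
            reads.append(reads[int(rng.integers(0, len(reads)))])
        else:
            parent = reads[int(rng.integers(0, len(reads)))]
            sub_len = int(rng.integers(1, len(parent) + 1))
            start = int(rng.integers(0, len(parent) - sub_len + 1))
            reads.append(parent[start : start + sub_len])
    return reads


def as_reads(sequences, quality: int = 40) -> list[SequenceRead]:
    return [
        SequenceRead(f"r{i}", seq, (quality,) * len(seq))
        for i, seq in enumerate(sequences)
    ]
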