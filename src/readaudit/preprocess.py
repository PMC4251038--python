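"""Read cleaning: adapter trimming, quality end-trimming, N-read removal.

The per-read pipeline is: adapter trim -> quality end trim -> drop the read
if it still contains an N -> drop it if shorter than ``min_length``. Raw and
cleaned read counters are maintained so that
``n_raw == n_cleaned + n_dropped_n + n_dropped_short`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ConsistencyError
from .io_formats import DEFAULT_PHRED_OFFSET, SequenceRead, read_fastq


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning parameters.

    adapter        3' adapter sequence; ``None`` disables adapter trimming.
    q_cutoff       Phred score below which terminal bases are trimmed (default 20).
    phred_offset   FASTQ quality encoding offset (default 33).
    min_length     minimum post-trim length; shorter reads are dropped
                   (default 1, i.e. only empty reads are dropped).
    min_overlap    minimum 3'-terminal adapter overlap to trigger trimming.
    max_error_rate maximum mismatch fraction allowed in an adapter match.
    """

    adapter: str | None = None
    q_cutoff: int = 20
    phred_offset: int = DEFAULT_PHRED_OFFSET
    min_length: int = 1
    min_overlap: int = 3
    max_error_rate: float = 0.1


@dataclass
class CleanReadSet:
    """A cleaned read collection plus the raw/cleaned/dropped ledger."""

    reads: list[SequenceRead]
    n_raw: int
    n_dropped_n: int
    n_dropped_short: int

    def __post_init__(self) -> None:
        if self.n_raw != self.n_cleaned + self.n_dropped_n + self.n_dropped_short:
            raise ConsistencyError(
                f"counter mismatch: raw {self.n_raw} != cleaned {self.n_cleaned} "
                f"+ dropped_n {self.n_dropped_n} + dropped_short {self.n_dropped_short}"
            )

    @property
    def n_cleaned(self) -> int:
        return len(self.reads)


def trim_quality_ends(read: SequenceRead, q_cutoff: int = 20) -> SequenceRead:
    """Trim low-quality bases from both ends.

    Bases are removed from the 5' and 3' ends while the terminal base quality
    is below ``q_cutoff``; interior bases are never touched. The result may
    be empty.
    """
    start = 0
    end = len(read.quals)
    while start < end and read.quals[start] < q_cutoff:
        start += 1
    while end > start and read.quals[end - 1] < q_cutoff:
        end -= 1
    if start == 0 and end == len(read.quals):
        return read
    return SequenceRead(read.read_id, read.bases[start:end], read.quals[start:end])


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(
    read: SequenceRead,
    adapter: str | None,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> SequenceRead:
    """Remove a 3' adapter match and everything 3' of it.

    A valid placement is either a full internal adapter match, or an adapter
    prefix overlapping the read's 3' terminus by at least ``min_overlap``
    bases, with mismatch fraction at most ``max_error_rate`` of the matched
    length. The leftmost valid placement wins (it removes the most sequence).
    With no adapter configured the read is returned unchanged.
    """
    if not adapter:
        return read
    bases = read.bases
    for start in range(len(bases)):
        overlap = min(len(adapter), len(bases) - start)
        if overlap < len(adapter) and overlap < min_overlap:
            break  # remaining placements are even shorter terminal overlaps
        if _mismatches(bases[start : start + overlap], adapter[:overlap]) <= (
            max_error_rate * overlap + 1e-9
        ):
            return SequenceRead(read.read_id, bases[:start], read.quals[:start])
    return read


def drop_n_reads(
    reads: Iterable[SequenceRead],
) -> tuple[list[SequenceRead], int]:
    """Remove reads containing at least one N; return survivors and the count removed."""
    kept: list[SequenceRead] = []
    removed = 0
    for read in reads:
        if "N" in read.bases:
            removed += 1
        else:
            kept.append(read)
    return kept, removed


def preprocess_reads(
    reads: Iterable[SequenceRead], config: PreprocessConfig = PreprocessConfig()
) -> CleanReadSet:
    """Run the cleaning pipeline over an in-memory read collection."""
    cleaned: list[SequenceRead] = []
    n_raw = 0
    n_dropped_n = 0
    n_dropped_short = 0
    for read in reads:
        n_raw += 1
        read = trim_adapter(
            read, config.adapter, config.min_overlap, config.max_error_rate
        )
        read = trim_quality_ends(read, config.q_cutoff)
        if "N" in read.bases:
            n_dropped_n += 1
        elif len(read) < config.min_length:
            n_dropped_short += 1
        else:
            cleaned.append(read)
    return CleanReadSet(
        reads=cleaned,
        n_raw=n_raw,
        n_dropped_n=n_dropped_n,
        n_dropped_short=n_dropped_short,
    )


def preprocess_run(
    path: str | Path, config: PreprocessConfig = PreprocessConfig()
) -> CleanReadSet:
    """Read a FASTQ file and run the cleaning pipeline over it."""
    return preprocess_reads(read_fastq(path, config.phred_offset), config)
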