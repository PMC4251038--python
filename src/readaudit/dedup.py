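"""Collapse a cleaned read set into unique sequences.

Two reads are *identical* when they match 100% and have equal length; an
*inclusive* read is an exact sub-sequence of a longer read — only the longest
read is kept as the unique read and it inherits the copies of everything it
contains. The redundancy rate is

    redundancy (%) = 100 * redundant reads / unique cleaned reads

and may exceed 100%.

Bookkeeping convention: duplicate copies of a *surviving* sequence count as
identical-removed; every copy of a sequence absorbed by containment counts as
inclusive-removed. This keeps ``n_input == n_unique + n_identical_removed +
n_inclusive_removed`` exact.

The engine inserts survivors in descending length order into an incremental
joined-text index and resolves each shorter sequence with a single leftmost
substring search, which by construction credits each absorbed sequence to its
longest container (ties broken lexicographically).
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import UndefinedRateError
from .io_formats import SequenceRead, write_unique_table
from .preprocess import CleanReadSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class UniqueSequence:
    """A surviving sequence and the number of reads collapsed into it."""

    sequence: str
    length: int
    count: int

    def __post_init__(self) -> None:
        assert self.length == len(self.sequence) and self.count >= 1


@dataclass(frozen=True)
class DedupResult:
    uniques: tuple[UniqueSequence, ...]
    n_input: int
    n_identical_removed: int
    n_inclusive_removed: int
    #: distinct sequences before containment removal ("after removing
    #: identical redundant reads" in run-comparison reports)
    n_distinct: int

    @property
    def n_unique(self) -> int:
        return len(self.uniques)

    @property
    def n_redundant(self) -> int:
        return self.n_identical_removed + self.n_inclusive_removed

    @property
    def redundancy_rate_pct(self) -> float:
        return redundancy_rate(self.n_redundant, self.n_unique)


class SubstringIndex:
    """Incremental exact-substring index over a growing set of sequences.

    Sequences are stored joined with a separator character; a leftmost
    ``str.find`` resolves a query to the earliest inserted member containing
    it. When members are inserted longest-first (ties lexicographic), the
    earliest container is the longest container with lexicographic
    tie-breaking — exactly the crediting rule used for inclusive reads.
    """

    _SEP = "#"

    def __init__(self) -> None:
        self._members: list[str] = []
        self._starts: list[int] = []
        self._joined = ""
        self._dirty = False

    def __len__(self) -> int:
        return len(self._members)

    def add(self, sequence: str) -> None:
        self._members.append(sequence)
        self._dirty = True

    def _rebuild(self) -> None:
        self._starts = []
        offset = 0
        for member in self._members:
            self._starts.append(offset)
            offset += len(member) + 1
        self._joined = self._SEP.join(self._members)
        self._dirty = False

    def find_container(self, query: str) -> int | None:
        """Index of the earliest inserted member containing ``query``, or None."""
        if self._dirty:
            self._rebuild()
        position = self._joined.find(query)
        if position == -1:
            return None
        return bisect_right(self._starts, position) - 1


def collapse_identical(
    reads: Iterable[SequenceRead | str], both_strands: bool = False
) -> dict[str, int]:
    """Map each distinct base-string to its multiplicity.

    With ``both_strands`` a read and its reverse complement are the same key
    (the lexicographically smaller orientation is kept).
    """
    counts: Counter[str] = Counter()
    for read in reads:
        sequence = read if isinstance(read, str) else read.bases
        if both_strands:
            sequence = min(sequence, reverse_complement(sequence))
        counts[sequence] += 1
    return dict(counts)


def remove_inclusive(
    distinct: Mapping[str, int], both_strands: bool = False
) -> DedupResult:
    """Absorb every sequence contained in a longer one; credit the longest container.

    Input keys must be distinct strings. The surviving set is substring-free.
    """
    n_input = sum(distinct.values())
    n_distinct = len(distinct)
    ordered = sorted(distinct, key=lambda s: (-len(s), s))
    index = SubstringIndex()
    survivors: list[str] = []
    counts: list[int] = []
    n_inclusive_removed = 0
    for sequence in ordered:
        container = index.find_container(sequence)
        if container is None and both_strands:
            container = index.find_container(reverse_complement(sequence))
        if container is None:
            index.add(sequence)
            survivors.append(sequence)
            counts.append(distinct[sequence])
        else:
            counts[container] += distinct[sequence]
            n_inclusive_removed += distinct[sequence]
    uniques = tuple(
        UniqueSequence(sequence=s, length=len(s), count=c)
        for s, c in zip(survivors, counts)
    )
    n_identical_removed = n_input - n_inclusive_removed - len(uniques)
    return DedupResult(
        uniques=uniques,
        n_input=n_input,
        n_identical_removed=n_identical_removed,
        n_inclusive_removed=n_inclusive_removed,
        n_distinct=n_distinct,
    )


def dedup_reads(
    reads: Iterable[SequenceRead | str], both_strands: bool = False
) -> DedupResult:
    """collapse_identical followed by remove_inclusive."""
    return remove_inclusive(collapse_identical(reads, both_strands), both_strands)


def redundancy_rate(n_redundant: int, n_unique: int) -> float:
    """Redundant reads as a percentage of unique cleaned reads (may exceed 100)."""
    if n_unique == 0:
        raise UndefinedRateError("redundancy rate undefined for zero unique reads")
    return 100.0 * n_redundant / n_unique


@dataclass(frozen=True)
class RunStatsReport:
    """The single-run statistics ledger."""

    n_raw: int
    n_cleaned: int
    dedup: DedupResult

    def summary_rows(self) -> list[tuple[str, object]]:
        return [
            ("Total number of raw reads in the run", self.n_raw),
            ("Total number of cleaned reads in the run", self.n_cleaned),
            (
                "Number of unique reads in the run (after removing identical redundant reads)",
                self.dedup.n_distinct,
            ),
            (
                "Number of unique reads in the run (after removing identical & inclusive redundant reads)",
                self.dedup.n_unique,
            ),
            ("Number of redundant cleaned reads in the run", self.dedup.n_redundant),
            (
                "Redundancy rate within the run",
                f"{self.dedup.redundancy_rate_pct:.1f}%",
            ),
        ]


def run_stats(
    clean: CleanReadSet,
    unique_table_path: str | Path | None = None,
    both_strands: bool = False,
) -> RunStatsReport:
    """Deduplicate a cleaned run and (optionally) write its unique-sequence table."""
    result = dedup_reads(clean.reads, both_strands)
    if unique_table_path is not None:
        write_unique_table(result.uniques, unique_table_path)
    return RunStatsReport(n_raw=clean.n_raw, n_cleaned=clean.n_cleaned, dedup=result)
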