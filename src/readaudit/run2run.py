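"""Compare two sequencing runs: overlapping reads and redundancy between runs.

Each run is cleaned and deduplicated independently; a unique sequence of one
run *overlaps* the other run when it is identical to, a substring of, or a
superstring of one of the other run's unique sequences. "Total overlapping
reads" is the cleaned-read mass (sum of copy counts) carried by a run's
overlapping uniques. The combined unique-overlap count merges both runs'
overlapping sets, collapsing cross-run identical and inclusive sequences.

All rate statistics share the shape of the single-run redundancy rate:
redundant reads divided by unique reads within the stratum, times 100.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .dedup import (
    DedupResult,
    UniqueSequence,
    dedup_reads,
    remove_inclusive,
    reverse_complement,
)
from .errors import ConsistencyError
from .io_formats import write_unique_table
from .preprocess import CleanReadSet


@dataclass(frozen=True)
class OverlapPartition:
    """Each run's unique set split into overlapping / non-overlapping parts."""

    overlapping_run1: tuple[UniqueSequence, ...]
    non_overlapping_run1: tuple[UniqueSequence, ...]
    overlapping_run2: tuple[UniqueSequence, ...]
    non_overlapping_run2: tuple[UniqueSequence, ...]

    @property
    def n_unique_overlap_run1(self) -> int:
        return len(self.overlapping_run1)

    @property
    def n_unique_overlap_run2(self) -> int:
        return len(self.overlapping_run2)


def _mark_overlaps(
    queries: Sequence[UniqueSequence],
    subjects: Sequence[UniqueSequence],
    query_flags: list[bool],
    subject_flags: list[bool],
    both_strands: bool,
) -> None:
    """Scan every query against the joined subject text.

    Every occurrence marks the query (it is a sub- or equal sequence of a
    subject) and the containing subject (it has a sub- or equal sequence in
    the queries).
    """
    if not subjects:
        return
    starts: list[int] = []
    offset = 0
    for subject in subjects:
        starts.append(offset)
        offset += subject.length + 1
    joined = "#".join(s.sequence for s in subjects)
    for qi, query in enumerate(queries):
        variants = [query.sequence]
        if both_strands:
            variants.append(reverse_complement(query.sequence))
        for variant in variants:
            position = joined.find(variant)
            while position != -1:
                query_flags[qi] = True
                subject_flags[bisect_right(starts, position) - 1] = True
                position = joined.find(variant, position + 1)


def cross_overlap(
    uniques_run1: Sequence[UniqueSequence],
    uniques_run2: Sequence[UniqueSequence],
    both_strands: bool = False,
) -> OverlapPartition:
    """Partition both runs' unique sets by cross-run identity/containment."""
    flags1 = [False] * len(uniques_run1)
    flags2 = [False] * len(uniques_run2)
    _mark_overlaps(uniques_run1, uniques_run2, flags1, flags2, both_strands)
    _mark_overlaps(uniques_run2, uniques_run1, flags2, flags1, both_strands)
    return OverlapPartition(
        overlapping_run1=tuple(u for u, f in zip(uniques_run1, flags1) if f),
        non_overlapping_run1=tuple(u for u, f in zip(uniques_run1, flags1) if not f),
        overlapping_run2=tuple(u for u, f in zip(uniques_run2, flags2) if f),
        non_overlapping_run2=tuple(u for u, f in zip(uniques_run2, flags2) if not f),
    )


def merge_overlap_union(
    overlapping_run1: Sequence[UniqueSequence],
    overlapping_run2: Sequence[UniqueSequence],
    both_strands: bool = False,
) -> tuple[int, tuple[UniqueSequence, ...]]:
    """Merge both runs' overlapping uniques into one substring-free set.

    Cross-run identical sequences are merged (counts summed) and cross-run
    inclusive sequences collapse to their longest container. Returns the
    merged unique count and the merged set.
    """
    counts: Counter[str] = Counter()
    for unique in (*overlapping_run1, *overlapping_run2):
        key = unique.sequence
        if both_strands:
            key = min(key, reverse_complement(key))
        counts[key] += unique.count
    merged = remove_inclusive(counts, both_strands)
    return merged.n_unique, merged.uniques


@dataclass(frozen=True)
class RunColumn:
    """One run's column of the run-comparison ledger (output + derived rows)."""

    n_raw: int
    n_cleaned: int
    n_unique_identical_only: int
    n_unique_full: int
    n_total_overlap: int
    n_unique_overlap: int

    def __post_init__(self) -> None:
        for name in (
            "n_redundant_cleaned",
            "n_total_nonoverlap",
            "n_unique_nonoverlap",
            "n_redundant_nonoverlap",
            "n_redundant_overlap",
        ):
            if getattr(self, name) < 0:
                raise ConsistencyError(f"negative derived count {name}")

    # -- derived statistics -------------------------------------------------
    @property
    def n_redundant_cleaned(self) -> int:
        return self.n_cleaned - self.n_unique_full

    @property
    def redundancy_rate_pct(self) -> float:
        return 100.0 * self.n_redundant_cleaned / self.n_unique_full

    @property
    def n_total_nonoverlap(self) -> int:
        return self.n_cleaned - self.n_total_overlap

    @property
    def n_unique_nonoverlap(self) -> int:
        return self.n_unique_full - self.n_unique_overlap

    @property
    def n_redundant_nonoverlap(self) -> int:
        return self.n_total_nonoverlap - self.n_unique_nonoverlap

    @property
    def nonoverlap_redundancy_pct(self) -> float:
        if self.n_unique_nonoverlap == 0:
            return 0.0
        return 100.0 * self.n_redundant_nonoverlap / self.n_unique_nonoverlap

    @property
    def n_redundant_overlap(self) -> int:
        return self.n_total_overlap - self.n_unique_overlap

    @property
    def overlap_redundancy_pct(self) -> float:
        if self.n_unique_overlap == 0:
            return 0.0
        return 100.0 * self.n_redundant_overlap / self.n_unique_overlap

    @property
    def overlap_over_cleaned_pct(self) -> float:
        return 100.0 * self.n_total_overlap / self.n_cleaned


def derived_from_counts(
    n_raw: int,
    n_cleaned: int,
    n_unique_identical_only: int,
    n_unique_full: int,
    n_total_overlap: int,
    n_unique_overlap: int,
) -> RunColumn:
    """Build one run's ledger column from its output-block counts.

    This is the derivation path for statistics reported per run: redundant
    read counts and redundancy rates overall and within the overlapping /
    non-overlapping strata.
    """
    return RunColumn(
        n_raw=n_raw,
        n_cleaned=n_cleaned,
        n_unique_identical_only=n_unique_identical_only,
        n_unique_full=n_unique_full,
        n_total_overlap=n_total_overlap,
        n_unique_overlap=n_unique_overlap,
    )


@dataclass(frozen=True)
class Run2RunStats:
    run1: RunColumn
    run2: RunColumn
    n_unique_overlap_both: int

    @property
    def overlap_over_cleaned_both_pct(self) -> float:
        total = self.run1.n_cleaned + self.run2.n_cleaned
        overlap = self.run1.n_total_overlap + self.run2.n_total_overlap
        return 100.0 * overlap / total if total else 0.0

    def summary_rows(self) -> list[tuple[str, object, object]]:
        r1, r2 = self.run1, self.run2
        return [
            ("Total number of raw reads in the run", r1.n_raw, r2.n_raw),
            ("Total number of cleaned reads in the run", r1.n_cleaned, r2.n_cleaned),
            (
                "Number of unique reads in the run (after removing identical redundant reads)",
                r1.n_unique_identical_only,
                r2.n_unique_identical_only,
            ),
            (
                "Number of unique reads in the run (after removing identical & inclusive redundant reads)",
                r1.n_unique_full,
                r2.n_unique_full,
            ),
            (
                "Total number of overlapping reads in the run",
                r1.n_total_overlap,
                r2.n_total_overlap,
            ),
            (
                "Number of unique overlapping reads in the run",
                r1.n_unique_overlap,
                r2.n_unique_overlap,
            ),
            (
                "Number of unique overlapping reads from both runs",
                self.n_unique_overlap_both,
                "",
            ),
            (
                "Number of redundant cleaned reads in the run",
                r1.n_redundant_cleaned,
                r2.n_redundant_cleaned,
            ),
            (
                "Redundancy rate within the run",
                f"{r1.redundancy_rate_pct:.1f}%",
                f"{r2.redundancy_rate_pct:.1f}%",
            ),
            (
                "Total number of non-overlapping reads in the run",
                r1.n_total_nonoverlap,
                r2.n_total_nonoverlap,
            ),
            (
                "Number of unique non-overlapping reads in the run",
                r1.n_unique_nonoverlap,
                r2.n_unique_nonoverlap,
            ),
            (
                "Number of redundant non-overlapping reads in the run",
                r1.n_redundant_nonoverlap,
                r2.n_redundant_nonoverlap,
            ),
            (
                "Redundancy of non-overlapping reads in the run",
                f"{r1.nonoverlap_redundancy_pct:.1f}%",
                f"{r2.nonoverlap_redundancy_pct:.1f}%",
            ),
            (
                "Number of redundant overlapping reads in the run",
                r1.n_redundant_overlap,
                r2.n_redundant_overlap,
            ),
            (
                "Redundancy of overlapping reads in the run",
                f"{r1.overlap_redundancy_pct:.1f}%",
                f"{r2.overlap_redundancy_pct:.1f}%",
            ),
            (
                "Total overlapping reads/total cleaned reads (each run)",
                f"{r1.overlap_over_cleaned_pct:.1f}%",
                f"{r2.overlap_over_cleaned_pct:.1f}%",
            ),
            (
                "Total overlapping reads/total cleaned reads (both runs)",
                f"{self.overlap_over_cleaned_both_pct:.1f}%",
                "",
            ),
        ]


@dataclass(frozen=True)
class Run2RunResult:
    stats: Run2RunStats
    partition: OverlapPartition
    dedup_run1: DedupResult
    dedup_run2: DedupResult
    merged_overlap: tuple[UniqueSequence, ...]


def _column(clean: CleanReadSet, dedup: DedupResult, overlapping) -> RunColumn:
    return derived_from_counts(
        n_raw=clean.n_raw,
        n_cleaned=clean.n_cleaned,
        n_unique_identical_only=dedup.n_distinct,
        n_unique_full=dedup.n_unique,
        n_total_overlap=sum(u.count for u in overlapping),
        n_unique_overlap=len(overlapping),
    )


def run2run_stats(
    clean_run1: CleanReadSet,
    clean_run2: CleanReadSet,
    out_dir: str | Path | None = None,
    both_strands: bool = False,
) -> Run2RunResult:
    """Full two-run comparison: dedup each run, cross-overlap, derived ledger.

    When ``out_dir`` is given, writes the stats table plus four unique-sequence
    tables (overlapping / non-overlapping for each run).
    """
    dedup1 = dedup_reads(clean_run1.reads, both_strands)
    dedup2 = dedup_reads(clean_run2.reads, both_strands)
    partition = cross_overlap(dedup1.uniques, dedup2.uniques, both_strands)
    n_both, merged = merge_overlap_union(
        partition.overlapping_run1, partition.overlapping_run2, both_strands
    )
    stats = Run2RunStats(
        run1=_column(clean_run1, dedup1, partition.overlapping_run1),
        run2=_column(clean_run2, dedup2, partition.overlapping_run2),
        n_unique_overlap_both=n_both,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_unique_table(partition.overlapping_run1, out_dir / "run1_overlapping.tsv")
        write_unique_table(
            partition.non_overlapping_run1, out_dir / "run1_nonoverlapping.tsv"
        )
        write_unique_table(partition.overlapping_run2, out_dir / "run2_overlapping.tsv")
        write_unique_table(
            partition.non_overlapping_run2, out_dir / "run2_nonoverlapping.tsv"
        )
        with open(out_dir / "run2run_stats.tsv", "wt") as handle:
            handle.write("statistic\trun1\trun2\n")
            for label, v1, v2 in stats.summary_rows():
                handle.write(f"{label}\t{v1}\t{v2}\n")
    return Run2RunResult(
        stats=stats,
        partition=partition,
        dedup_run1=dedup1,
        dedup_run2=dedup2,
        merged_overlap=merged,
    )


__all__ = [
    "OverlapPartition",
    "cross_overlap",
    "merge_overlap_union",
    "RunColumn",
    "derived_from_counts",
    "Run2RunStats",
    "Run2RunResult",
    "run2run_stats",
]
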