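"""Reference coverage from alignments: per-base depth, breadth, depth, evenness.

Definitions, applied per scaffold and genome-wide:

    breadth (%)  = 100 * reference bases covered by >=1 read / reference length
    depth        = total bases mapped to the reference / reference length
    evenness     = SD(scaffold breadths) / mean(scaffold breadths)

The standard deviation is the population SD over ALL scaffolds, including
zero-coverage ones. CIGAR ops M/=/X cover reference bases; D and N advance
the reference cursor without covering; I/S/H/P consume no reference.

Records flagged unmapped (0x4), secondary (0x100) or supplementary (0x800)
are excluded from depth accumulation and from the mapped-read count, so each
read contributes at most one primary placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConsistencyError, ReadAuditError, UnknownReferenceError
from .io_formats import (
    AlignmentRecord,
    ReferenceScaffold,
    SequenceRead,
    parse_cigar,
    parse_sam,
    write_depth_track,
)

_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x800

#: Depth histogram bin upper edges; the last bin is open above the final edge.
DEFAULT_DEPTH_EDGES = (1, 2, 4, 10)


def cigar_reference_intervals(
    pos: int, cigar: str
) -> tuple[list[tuple[int, int]], int]:
    """Reference intervals covered by an alignment, plus its reference span.

    ``pos`` is the 1-based leftmost mapping position; returned intervals are
    half-open 0-based. Adjacent covered intervals (e.g. across an insertion)
    are merged.
    """
    cursor = pos - 1
    intervals: list[tuple[int, int]] = []
    for length, op in parse_cigar(cigar):
        if op in "M=X":
            if intervals and intervals[-1][1] == cursor:
                intervals[-1] = (intervals[-1][0], cursor + length)
            else:
                intervals.append((cursor, cursor + length))
            cursor += length
        elif op in "DN":
            cursor += length
    return intervals, cursor - (pos - 1)


def accumulate_depth(
    alignments: Iterable[AlignmentRecord], scaffolds: Sequence[ReferenceScaffold]
) -> tuple[dict[str, np.ndarray], int]:
    """Per-scaffold per-base depth arrays and the primary mapped-read count."""
    depths = {s.name: np.zeros(s.length, dtype=np.int64) for s in scaffolds}
    n_reads_mapped = 0
    for record in alignments:
        if record.flag & _EXCLUDE_FLAGS or not record.usable:
            continue
        if record.rname not in depths:
            raise UnknownReferenceError(
                f"alignment references unknown scaffold {record.rname!r}"
            )
        depth = depths[record.rname]
        intervals, _ = cigar_reference_intervals(record.pos, record.cigar)
        for start, end in intervals:
            if end > len(depth) or start < 0:
                raise ConsistencyError(
                    f"alignment at {record.rname}:{record.pos} ({record.cigar}) "
                    f"extends past scaffold end {len(depth)}"
                )
            depth[start:end] += 1
        n_reads_mapped += 1
    return depths, n_reads_mapped


@dataclass(frozen=True)
class ScaffoldCoverage:
    name: str
    length: int
    covered_bases: int
    mapped_bases: int

    @property
    def breadth_pct(self) -> float:
        return 100.0 * self.covered_bases / self.length

    @property
    def depth_mean(self) -> float:
        return self.mapped_bases / self.length

    @classmethod
    def from_depth(cls, name: str, depth: np.ndarray) -> "ScaffoldCoverage":
        return cls(
            name=name,
            length=int(depth.size),
            covered_bases=int(np.count_nonzero(depth)),
            mapped_bases=int(depth.sum()),
        )


@dataclass(frozen=True)
class CoverageSummary:
    n_scaffolds_total: int
    n_scaffolds_covered: int
    covered_scaffold_pct: float
    genome_breadth_pct: float
    genome_depth: float
    evenness: float
    breadth_mean: float
    breadth_sd: float
    depth_mean: float
    depth_sd: float
    n_reads_mapped: int
    mapped_over_cleaned_pct: float

    def summary_rows(self) -> list[tuple[str, object]]:
        return [
            ("Total number of reads mapped to reference genome", self.n_reads_mapped),
            ("Mapped/Cleaned reads (%)", f"{self.mapped_over_cleaned_pct:.2f}"),
            ("Total number of scaffolds in reference genome", self.n_scaffolds_total),
            ("Number of covered reference scaffolds", self.n_scaffolds_covered),
            ("Covered/Total scaffolds (%)", f"{self.covered_scaffold_pct:.2f}"),
            ("Genome coverage breadth (%)", f"{self.genome_breadth_pct:.2f}"),
            ("Genome coverage depth", f"{self.genome_depth:.2f}"),
            ("standard deviation of scaffold coverage depth", f"{self.depth_sd:.2f}"),
            ("average scaffold coverage depth", f"{self.depth_mean:.2f}"),
            ("Genome coverage evenness", f"{self.evenness:.2f}"),
        ]


def covered_scaffold_pct(n_covered: int, n_total: int) -> float:
    if n_total == 0:
        raise ReadAuditError("empty reference genome")
    return 100.0 * n_covered / n_total


def mapped_over_cleaned_pct(n_mapped: int, n_cleaned: int) -> float:
    return 100.0 * n_mapped / n_cleaned if n_cleaned else float("nan")


def summarize_coverage(
    depths: dict[str, np.ndarray],
    scaffolds: Sequence[ReferenceScaffold],
    n_reads_mapped: int,
    n_cleaned: int,
) -> tuple[CoverageSummary, list[ScaffoldCoverage]]:
    """Coverage statistics genome-wide and per scaffold.

    Standard deviations are population SDs over all scaffolds (zero-coverage
    scaffolds included).
    """
    if not scaffolds:
        raise ReadAuditError("empty reference genome")
    per_scaffold = [
        ScaffoldCoverage.from_depth(s.name, depths[s.name]) for s in scaffolds
    ]
    breadths = np.array([s.breadth_pct for s in per_scaffold])
    depth_means = np.array([s.depth_mean for s in per_scaffold])
    total_length = sum(s.length for s in per_scaffold)
    total_covered = sum(s.covered_bases for s in per_scaffold)
    total_mapped = sum(s.mapped_bases for s in per_scaffold)
    n_covered = sum(1 for s in per_scaffold if s.covered_bases >= 1)
    breadth_mean = float(breadths.mean())
    breadth_sd = float(breadths.std())
    summary = CoverageSummary(
        n_scaffolds_total=len(per_scaffold),
        n_scaffolds_covered=n_covered,
        covered_scaffold_pct=covered_scaffold_pct(n_covered, len(per_scaffold)),
        genome_breadth_pct=100.0 * total_covered / total_length,
        genome_depth=total_mapped / total_length,
        evenness=breadth_sd / breadth_mean if breadth_mean else float("nan"),
        breadth_mean=breadth_mean,
        breadth_sd=breadth_sd,
        depth_mean=float(depth_means.mean()),
        depth_sd=float(depth_means.std()),
        n_reads_mapped=n_reads_mapped,
        mapped_over_cleaned_pct=mapped_over_cleaned_pct(n_reads_mapped, n_cleaned),
    )
    return summary, per_scaffold


def bin_distributions(
    per_scaffold: Sequence[ScaffoldCoverage],
    depth_edges: Sequence[float] = DEFAULT_DEPTH_EDGES,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Histogram scaffolds by coverage breadth and by mean depth.

    Bins are open at the lower end and closed at the higher end, with a
    dedicated bin for zero coverage: breadth uses {0}, (0,10], ..., (90,100]
    in percent; depth uses {0}, (0,e1], (e1,e2], ..., (e_last,inf).
    """
    breadth_labels = ["0"] + [f"({10 * k},{10 * (k + 1)}]" for k in range(10)]
    breadth_counts = [0] * 11
    edges = list(depth_edges)
    depth_labels = (
        ["0"]
        + [f"({lo:g},{hi:g}]" for lo, hi in zip([0] + edges[:-1], edges)]
        + [f"({edges[-1]:g},inf)"]
    )
    depth_counts = [0] * (len(edges) + 2)
    for scaffold in per_scaffold:
        if scaffold.covered_bases == 0:
            breadth_counts[0] += 1
        else:
            # integer arithmetic: smallest k with covered/length <= k/10
            k = -(-10 * scaffold.covered_bases // scaffold.length)
            breadth_counts[k] += 1
        if scaffold.mapped_bases == 0:
            depth_counts[0] += 1
        else:
            for i, edge in enumerate(edges):
                if scaffold.mapped_bases <= edge * scaffold.length:
                    depth_counts[i + 1] += 1
                    break
            else:
                depth_counts[-1] += 1
    return (
        list(zip(breadth_labels, breadth_counts)),
        list(zip(depth_labels, depth_counts)),
    )


def exact_match_align(
    reads: Iterable[SequenceRead], scaffolds: Sequence[ReferenceScaffold]
) -> list[AlignmentRecord]:
    """Exact full-length forward-strand aligner.

    Each read is reported at every exact occurrence across the reference as
    (flag 0, scaffold, pos, "<len>M"); the first occurrence (reference order,
    then position) is primary, later ones are flagged secondary (0x100). Reads
    with no occurrence are reported unmapped (flag 0x4). Intended for testing
    and small fixtures; real analyses should supply a SAM from a production
    aligner.
    """
    for scaffold in scaffolds:
        if scaffold.sequence is None:
            raise ConsistencyError(
                f"scaffold {scaffold.name!r} lacks sequence; cannot align"
            )
    records: list[AlignmentRecord] = []
    for read in reads:
        hits: list[tuple[str, int]] = []
        for scaffold in scaffolds:
            start = scaffold.sequence.find(read.bases)
            while start != -1:
                hits.append((scaffold.name, start + 1))
                start = scaffold.sequence.find(read.bases, start + 1)
        if not hits:
            records.append(AlignmentRecord(flag=0x4, rname="*", pos=0, cigar="*"))
            continue
        cigar = f"{len(read.bases)}M"
        for i, (name, pos) in enumerate(hits):
            records.append(
                AlignmentRecord(
                    flag=0 if i == 0 else 0x100, rname=name, pos=pos, cigar=cigar
                )
            )
    return records


@dataclass(frozen=True)
class Run2RefResult:
    summary: CoverageSummary
    per_scaffold: list[ScaffoldCoverage]
    depths: dict[str, np.ndarray]
    breadth_hist: list[tuple[str, int]]
    depth_hist: list[tuple[str, int]]
    n_cleaned: int


def run2ref(
    scaffolds: Sequence[ReferenceScaffold],
    reads: Iterable[SequenceRead] | None = None,
    sam_path: str | Path | None = None,
    n_cleaned: int | None = None,
    depth_edges: Sequence[float] = DEFAULT_DEPTH_EDGES,
) -> Run2RefResult:
    """Genome-coverage analysis of one run against a reference.

    Supply either ``sam_path`` (alignments from any external aligner; only
    FLAG/RNAME/POS/CIGAR are consumed) or ``reads`` (aligned internally with
    the exact-match aligner, which requires scaffold sequences).
    """
    if (reads is None) == (sam_path is None):
        raise ReadAuditError("provide exactly one of reads or sam_path")
    if sam_path is not None:
        header_scaffolds, alignments = parse_sam(sam_path)
        if scaffolds:
            by_name = {s.name: s for s in scaffolds}
            for hs in header_scaffolds:
                if hs.name in by_name and by_name[hs.name].length != hs.length:
                    raise ConsistencyError(
                        f"scaffold {hs.name!r}: SAM header length {hs.length} "
                        f"!= reference length {by_name[hs.name].length}"
                    )
        else:
            scaffolds = header_scaffolds
        alignments = list(alignments)
    else:
        reads = list(reads)
        if n_cleaned is None:
            n_cleaned = len(reads)
        alignments = exact_match_align(reads, scaffolds)
    if n_cleaned is None:
        n_cleaned = sum(1 for a in alignments if not (a.flag & (0x100 | 0x800)))
    depths, n_reads_mapped = accumulate_depth(alignments, scaffolds)
    summary, per_scaffold = summarize_coverage(
        depths, scaffolds, n_reads_mapped, n_cleaned
    )
    breadth_hist, depth_hist = bin_distributions(per_scaffold, depth_edges)
    return Run2RefResult(
        summary=summary,
        per_scaffold=per_scaffold,
        depths=depths,
        breadth_hist=breadth_hist,
        depth_hist=depth_hist,
        n_cleaned=n_cleaned,
    )


def write_per_scaffold_table(
    per_scaffold: Sequence[ScaffoldCoverage], path: str | Path
) -> None:
    with open(path, "wt") as handle:
        handle.write("scaffold\tlength\tcovered_bases\tmapped_bases\tbreadth_pct\tdepth\n")
        for s in per_scaffold:
            handle.write(
                f"{s.name}\t{s.length}\t{s.covered_bases}\t{s.mapped_bases}"
                f"\t{s.breadth_pct:.2f}\t{s.depth_mean:.2f}\n"
            )


def write_histograms(
    breadth_hist: Sequence[tuple[str, int]],
    depth_hist: Sequence[tuple[str, int]],
    path: str | Path,
) -> None:
    with open(path, "wt") as handle:
        handle.write("metric\tbin\tn_scaffolds\n")
        for label, count in breadth_hist:
            handle.write(f"breadth\t{label}\t{count}\n")
        for label, count in depth_hist:
            handle.write(f"depth\t{label}\t{count}\n")


def write_summary(summary: CoverageSummary, n_cleaned: int, path: str | Path) -> None:
    with open(path, "wt") as handle:
        handle.write(f"Total number of cleaned reads\t{n_cleaned}\n")
        for label, value in summary.summary_rows():
            handle.write(f"{label}\t{value}\n")


__all__ = [
    "cigar_reference_intervals",
    "accumulate_depth",
    "ScaffoldCoverage",
    "CoverageSummary",
    "covered_scaffold_pct",
    "mapped_over_cleaned_pct",
    "summarize_coverage",
    "bin_distributions",
    "exact_match_align",
    "Run2RefResult",
    "run2ref",
    "write_per_scaffold_table",
    "write_histograms",
    "write_summary",
    "write_depth_track",
]
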