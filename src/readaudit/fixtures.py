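"""Synthetic datasets with known ground truth.

The flagship fixture mirrors a classic validation design for run-auditing
tools: 10 artificial chromosomes of 150 bp are clipped from a source genome,
10 read templates of 75-100 bp are clipped from each chromosome, and every
template is emitted 10 times — 1,000 reads total. The template set is
regenerated until pairwise substring-free, so the expected truth is exactly
100 unique sequences with copy number 10 each, and the covered reference
intervals are the recorded clip windows.

By default the source genome is a seeded random 5-kb sequence so no download
is ever needed; any user FASTA can be supplied instead to reproduce the
original construction on a real genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ReadAuditError
from .io_formats import ReferenceScaffold, SequenceRead, write_fasta, write_fastq

_BASES = np.array(list("ACGT"))

#: Constant read quality used for synthetic reads (Phred 40).
SYNTHETIC_QUALITY = 40

N_CHROMOSOMES = 10
CHROMOSOME_LENGTH = 150
TEMPLATES_PER_CHROMOSOME = 10
TEMPLATE_LENGTH_RANGE = (75, 100)
COPIES_PER_TEMPLATE = 10


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded while generating a synthetic dataset."""

    #: (source_name, start, end) half-open 0-based window per chromosome
    chromosome_windows: tuple[tuple[str, int, int], ...]
    #: (chromosome, start, end) half-open 0-based window per read template
    read_windows: tuple[tuple[str, int, int], ...]
    copies_per_template: int
    expected_n_unique: int
    #: template sequence -> expected collapsed copy number
    expected_counts: dict[str, int]
    #: chromosome -> merged covered intervals (half-open 0-based)
    expected_covered: dict[str, tuple[tuple[int, int], ...]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "chromosome_windows": list(self.chromosome_windows),
                "read_windows": list(self.read_windows),
                "copies_per_template": self.copies_per_template,
                "expected_n_unique": self.expected_n_unique,
                "expected_counts": self.expected_counts,
                "expected_covered": {
                    k: list(v) for k, v in self.expected_covered.items()
                },
            },
            indent=1,
        )


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _merge_intervals(
    intervals: Sequence[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return tuple(merged)


def _substring_free(sequences: Sequence[str]) -> bool:
    for i, a in enumerate(sequences):
        for j, b in enumerate(sequences):
            if i != j and a in b:
                return False
    return True


def _staircase_windows(
    length: int,
    n: int,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    max_retries: int,
) -> list[tuple[int, int]]:
    """Draw ``n`` windows of length lo..hi with strictly increasing starts
    AND ends, so no window is an interval-containment of another.

    Random windows of near-chromosome length almost surely contain one
    another; the staircase layout keeps positions and lengths random while
    guaranteeing the clipped sequences stay pairwise non-nested.
    """
    max_start = length - hi
    if max_start + 1 < n:
        raise ReadAuditError("chromosome too short for the requested windows")
    for _ in range(max_retries):
        starts = sorted(rng.choice(max_start + 1, size=n, replace=False).tolist())
        ends: list[int] = []
        feasible = True
        for start in starts:
            low_end = max(start + lo, (ends[-1] + 1) if ends else 0)
            high_end = min(start + hi, length)
            if low_end > high_end:
                feasible = False
                break
            ends.append(int(rng.integers(low_end, high_end + 1)))
        if feasible:
            return list(zip(starts, ends))
    raise ReadAuditError("could not draw non-nested clip windows")


def make_paper_synthetic(
    seed: int = 0,
    source: ReferenceScaffold | None = None,
    out_dir: str | Path | None = None,
    max_retries: int = 100,
) -> tuple[list[ReferenceScaffold], list[SequenceRead], SyntheticTruth]:
    """Build the 10-chromosome / 1,000-read validation dataset.

    The source genome (default: seeded random 5 kb) is clipped into 10
    disjoint 150-bp chromosomes; 10 templates of 75-100 bp are clipped from
    each chromosome and emitted 10x at constant Q40. Template sets are
    redrawn until pairwise substring-free so the dedup truth is exact.
    """
    rng = np.random.default_rng(seed)
    if source is None:
        source = ReferenceScaffold(
            name="synthetic_source",
            length=5000,
            sequence=random_genome(5000, rng),
        )
    if source.sequence is None or source.length < N_CHROMOSOMES * CHROMOSOME_LENGTH:
        raise ReadAuditError(
            f"source must carry sequence and be at least "
            f"{N_CHROMOSOMES * CHROMOSOME_LENGTH} bp long"
        )
    # one chromosome window inside each of 10 equal source blocks (disjoint loci)
    block = source.length // N_CHROMOSOMES
    chrom_windows: list[tuple[str, int, int]] = []
    scaffolds: list[ReferenceScaffold] = []
    for i in range(N_CHROMOSOMES):
        start = i * block + int(rng.integers(0, block - CHROMOSOME_LENGTH + 1))
        end = start + CHROMOSOME_LENGTH
        chrom_windows.append((source.name, start, end))
        scaffolds.append(
            ReferenceScaffold(
                name=f"chr{i + 1:02d}",
                length=CHROMOSOME_LENGTH,
                sequence=source.sequence[start:end],
            )
        )

    lo, hi = TEMPLATE_LENGTH_RANGE
    for _ in range(max_retries):
        read_windows: list[tuple[str, int, int]] = []
        templates: list[str] = []
        for scaffold in scaffolds:
            windows = _staircase_windows(
                scaffold.length, TEMPLATES_PER_CHROMOSOME, lo, hi, rng, max_retries
            )
            for start, end in windows:
                read_windows.append((scaffold.name, start, end))
                templates.append(scaffold.sequence[start:end])
        if len(set(templates)) == len(templates) and _substring_free(templates):
            break
    else:
        raise ReadAuditError("could not draw a substring-free template set")

    reads: list[SequenceRead] = []
    for t, (template, (chrom, start, _)) in enumerate(zip(templates, read_windows)):
        quals = (SYNTHETIC_QUALITY,) * len(template)
        for copy in range(COPIES_PER_TEMPLATE):
            reads.append(
                SequenceRead(
                    read_id=f"{chrom}_t{t % TEMPLATES_PER_CHROMOSOME:02d}"
                    f"_p{start}_c{copy:02d}",
                    bases=template,
                    quals=quals,
                )
            )

    covered: dict[str, tuple[tuple[int, int], ...]] = {}
    for scaffold in scaffolds:
        covered[scaffold.name] = _merge_intervals(
            [(s, e) for chrom, s, e in read_windows if chrom == scaffold.name]
        )
    truth = SyntheticTruth(
        chromosome_windows=tuple(chrom_windows),
        read_windows=tuple(read_windows),
        copies_per_template=COPIES_PER_TEMPLATE,
        expected_n_unique=len(templates),
        expected_counts={t: COPIES_PER_TEMPLATE for t in templates},
        expected_covered=covered,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(scaffolds, out_dir / "reference.fasta")
        write_fastq(reads, out_dir / "reads.fastq")
        (out_dir / "truth.json").write_text(truth.to_json())
    return scaffolds, reads, truth


def split_halves(
    reads: Sequence[SequenceRead],
) -> tuple[list[SequenceRead], list[SequenceRead]]:
    """Interleaved split into two runs (reads alternate between halves).

    With templates emitted as consecutive copy blocks of even size, both
    halves receive the same number of copies of every template, so a two-run
    comparison of the halves shows complete overlap.
    """
    if len(reads) % 2:
        raise ReadAuditError("cannot split an odd number of reads into halves")
    return list(reads[0::2]), list(reads[1::2])


@dataclass(frozen=True)
class RandomInstanceTruth:
    """Expected dedup outcome for a randomized instance."""

    templates: tuple[str, ...]
    copies: tuple[int, ...]
    expected_uniques: dict[str, int]

    @property
    def expected_n_unique(self) -> int:
        return len(self.expected_uniques)


def random_instance(
    n_templates: int,
    length_range: tuple[int, int] = (20, 40),
    copy_range: tuple[int, int] = (1, 5),
    containment_fraction: float = 0.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> tuple[list[SequenceRead], RandomInstanceTruth]:
    """Randomized dedup instance with a planted containment structure.

    ``containment_fraction`` of the templates are drawn as proper substrings
    of the remaining base templates; base templates are redrawn until pairwise
    substring-free and each planted substring is contained in exactly one
    base template, so the expected unique set and copy counters are exact.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    n_planted = int(round(containment_fraction * n_templates))
    n_base = n_templates - n_planted
    if n_base < 1:
        raise ReadAuditError("containment fraction leaves no base templates")

    for _ in range(max_retries):
        bases = [
            "".join(_BASES[rng.integers(0, 4, size=rng.integers(lo, hi + 1))])
            for _ in range(n_base)
        ]
        if len(set(bases)) == n_base and _substring_free(bases):
            break
    else:
        raise ReadAuditError("could not draw a substring-free base template set")

    planted: list[tuple[str, int]] = []  # (substring, parent index)
    attempts = 0
    while len(planted) < n_planted:
        attempts += 1
        if attempts > max_retries * max(1, n_planted):
            raise ReadAuditError("could not plant unambiguous substrings")
        parent = int(rng.integers(0, n_base))
        parent_seq = bases[parent]
        if len(parent_seq) < 2:
            continue
        sub_len = int(rng.integers(max(1, lo // 2), len(parent_seq)))
        start = int(rng.integers(0, len(parent_seq) - sub_len + 1))
        sub = parent_seq[start : start + sub_len]
        containers = [i for i, b in enumerate(bases) if sub in b]
        if containers != [parent]:
            continue  # ambiguous or duplicate placement; redraw
        if any(sub == p or sub in p or p in sub for p, _ in planted):
            continue
        planted.append((sub, parent))

    templates = bases + [sub for sub, _ in planted]
    copies = [int(rng.integers(copy_range[0], copy_range[1] + 1)) for _ in templates]
    expected: dict[str, int] = {
        b: c for b, c in zip(bases, copies[:n_base])
    }
    for (sub, parent), count in zip(planted, copies[n_base:]):
        expected[bases[parent]] += count

    reads: list[SequenceRead] = []
    for t, (template, count) in enumerate(zip(templates, copies)):
        quals = (SYNTHETIC_QUALITY,) * len(template)
        for copy in range(count):
            reads.append(
                SequenceRead(
                    read_id=f"t{t:03d}_c{copy:02d}", bases=template, quals=quals
                )
            )
    truth = RandomInstanceTruth(
        templates=tuple(templates),
        copies=tuple(copies),
        expected_uniques=expected,
    )
    return reads, truth
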