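"""Readers and writers for the formats the toolkit consumes and emits.

Input formats: FASTQ (plain or gzip), FASTA, and a subset of SAM (header
``@SQ`` lines plus columns FLAG, RNAME, POS and CIGAR of each alignment).
Output formats: the tab-delimited unique-sequence table and the per-base
depth track.

FASTA/FASTQ parsing is delegated to Biopython; SAM alignment lines are
column-extracted directly (only FLAG/RNAME/POS/CIGAR are consumed, and an
alignment naming a scaffold absent from the header must be a hard error
rather than a silent unmapped downgrade).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import (
    ConsistencyError,
    FormatError,
    MalformedRecordError,
    TruncatedFileError,
    UnknownReferenceError,
)

DEFAULT_PHRED_OFFSET = 33

#: CIGAR grammar: run length followed by one operation character.
CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

UNIQUE_TABLE_COLUMNS = ("sequence_id", "length", "count", "sequence")


@dataclass(frozen=True)
class SequenceRead:
    """One FASTQ record: identifier, bases and decoded Phred qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise MalformedRecordError(
                f"read {self.read_id!r}: sequence length {len(self.bases)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignmentRecord:
    """The SAM fields the toolkit consumes: FLAG, RNAME, POS (1-based), CIGAR."""

    flag: int
    rname: str
    pos: int
    cigar: str

    @property
    def usable(self) -> bool:
        """True when the record carries a concrete placement on a reference."""
        return not (self.flag & 0x4) and self.rname != "*" and self.cigar != "*"


@dataclass(frozen=True)
class ReferenceScaffold:
    """One reference sequence unit (contig, chromosome or gene model).

    ``sequence`` is absent when only header lengths are available (SAM @SQ).
    """

    name: str
    length: int
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise FormatError(f"scaffold {self.name!r} has zero length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ConsistencyError(
                f"scaffold {self.name!r}: declared length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) pairs, validating the grammar."""
    if not cigar or cigar == "*":
        raise FormatError(f"unparseable CIGAR {cigar!r}")
    pairs = CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in pairs) != cigar:
        raise FormatError(f"unparseable CIGAR {cigar!r}")
    return [(int(n), op) for n, op in pairs]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(
    path: str | Path, phred_offset: int = DEFAULT_PHRED_OFFSET
) -> Iterator[SequenceRead]:
    """Stream SequenceReads from a FASTQ file (plain or gzip) in file order.

    Raises :class:`MalformedRecordError` when a record's sequence and quality
    lengths differ and :class:`TruncatedFileError` when the file ends inside a
    record; both errors name the 0-based record index.
    """
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                message = f"record {index}: {exc}"
                if "length" in str(exc).lower():
                    raise MalformedRecordError(message) from exc
                raise TruncatedFileError(message) from exc
            read_id = title.split()[0] if title.strip() else ""
            yield SequenceRead(
                read_id=read_id,
                bases=seq.upper(),
                quals=tuple(ord(c) - phred_offset for c in qual),
            )
            index += 1


def write_fastq(
    reads: Iterable[SequenceRead],
    path: str | Path,
    phred_offset: int = DEFAULT_PHRED_OFFSET,
) -> None:
    """Write reads as 4-line FASTQ records."""
    with open(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + phred_offset) for q in read.quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[ReferenceScaffold]:
    """Read a (multi-)FASTA into scaffolds, preserving file order.

    Names are the header token up to the first whitespace; sequences are
    uppercased. Zero-length scaffolds and sequence data before any header are
    format errors.
    """
    scaffolds: list[ReferenceScaffold] = []
    with _open_text(path) as handle:
        first = handle.read(1)
        if first and first not in ">;\n":
            raise FormatError(f"{path}: sequence data before any FASTA header")
        handle.seek(0)
        try:
            for record in SeqIO.parse(handle, "fasta"):
                sequence = str(record.seq).upper()
                if not sequence:
                    raise FormatError(
                        f"{path}: zero-length scaffold {record.id!r}"
                    )
                scaffolds.append(
                    ReferenceScaffold(
                        name=record.id, length=len(sequence), sequence=sequence
                    )
                )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return scaffolds


def write_fasta(scaffolds: Iterable[ReferenceScaffold], path: str | Path) -> None:
    with open(path, "wt") as handle:
        for scaffold in scaffolds:
            if scaffold.sequence is None:
                raise ConsistencyError(
                    f"scaffold {scaffold.name!r} has no sequence to write"
                )
            handle.write(f">{scaffold.name}\n{scaffold.sequence}\n")


def parse_sam(
    path: str | Path,
) -> tuple[list[ReferenceScaffold], Iterator[AlignmentRecord]]:
    """Parse a SAM file into (@SQ scaffolds, stream of alignment records).

    Only the fields the toolkit consumes are extracted: @SQ SN/LN from the
    header and FLAG, RNAME, POS, CIGAR (columns 2, 3, 4, 6) from each
    alignment line; every optional field and every other header line is
    tolerated and ignored. Header scaffolds carry name and length only.
    Records with RNAME ``*`` or CIGAR ``*`` are yielded with
    ``usable == False``. An alignment naming a scaffold absent from the
    header raises :class:`UnknownReferenceError` (SAM parsers that silently
    treat such records as unmapped would hide upstream reference mixups).
    """
    handle = _open_text(path)
    scaffolds: list[ReferenceScaffold] = []
    names: set[str] = set()
    first_alignment: str | None = None
    for line in handle:
        if not line.strip():
            continue
        if not line.startswith("@"):
            first_alignment = line
            break
        if line.startswith("@SQ"):
            tags = dict(
                field.split(":", 1) for field in line.rstrip("\n").split("\t")[1:]
                if ":" in field
            )
            if "SN" not in tags or "LN" not in tags:
                raise FormatError(f"{path}: @SQ line lacks SN or LN: {line!r}")
            scaffolds.append(
                ReferenceScaffold(name=tags["SN"], length=int(tags["LN"]))
            )
            names.add(tags["SN"])

    def _record(line: str) -> AlignmentRecord:
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise MalformedRecordError(
                f"{path}: alignment line has {len(fields)} fields: {line!r}"
            )
        flag, rname, pos, cigar = int(fields[1]), fields[2], int(fields[3]), fields[5]
        if rname != "*" and rname not in names:
            raise UnknownReferenceError(
                f"{path}: alignment references scaffold {rname!r} absent from header"
            )
        return AlignmentRecord(flag=flag, rname=rname, pos=pos, cigar=cigar)

    def records() -> Iterator[AlignmentRecord]:
        with handle:
            if first_alignment is not None:
                yield _record(first_alignment)
                for line in handle:
                    if line.strip():
                        yield _record(line)

    return scaffolds, records()


def write_unique_table(uniques: Iterable, path: str | Path) -> None:
    """Write unique sequences as TSV: sequence_id, length, count, sequence.

    Rows are sorted by descending count, then descending length, then
    lexicographic sequence, so output is byte-reproducible; ids are assigned
    after sorting (u1, u2, ...).
    """
    ordered = sorted(uniques, key=lambda u: (-u.count, -u.length, u.sequence))
    with open(path, "wt") as handle:
        handle.write("\t".join(UNIQUE_TABLE_COLUMNS) + "\n")
        for i, unique in enumerate(ordered, start=1):
            handle.write(f"u{i}\t{unique.length}\t{unique.count}\t{unique.sequence}\n")


def read_unique_table(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a unique-sequence table back as (id, length, count, sequence) rows."""
    rows: list[tuple[str, int, int, str]] = []
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != UNIQUE_TABLE_COLUMNS:
            raise FormatError(f"{path}: unexpected unique-table header {header}")
        for line in handle:
            seq_id, length, count, sequence = line.rstrip("\n").split("\t")
            rows.append((seq_id, int(length), int(count), sequence))
    return rows


def write_depth_track(
    depths: dict[str, Sequence[int]],
    scaffolds: Sequence[ReferenceScaffold],
    path: str | Path,
    emit_zeros: bool = False,
) -> None:
    """Write the per-base depth track: scaffold, 1-based position, depth.

    Positions with zero depth are included only when ``emit_zeros`` is set
    (default off, to bound file size). Scaffolds appear in reference order.
    """
    with open(path, "wt") as handle:
        for scaffold in scaffolds:
            depth = depths[scaffold.name]
            if len(depth) != scaffold.length:
                raise ConsistencyError(
                    f"scaffold {scaffold.name!r}: depth array length "
                    f"{len(depth)} != scaffold length {scaffold.length}"
                )
            for position, value in enumerate(depth, start=1):
                if value or emit_zeros:
                    handle.write(f"{scaffold.name}\t{position}\t{int(value)}\n")
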