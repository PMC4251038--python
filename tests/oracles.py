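"""Brute-force reference implementations used to validate the engines.

These deliberately favour clarity over speed and share no code with the
package's optimized paths: dedup is an exhaustive pairwise substring scan,
depth accumulation walks every CIGAR op one base at a time, and cross-run
overlap tests every pair of unique sequences.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Sequence

_CIGAR = re.compile(r"(\d+)([MIDNSHP=X])")


def dedup_oracle(sequences: Iterable[str]) -> dict:
    """Exhaustive identical+inclusive collapse.

    Survivors are sequences not a proper substring of any other distinct
    sequence; each removed sequence's copies are credited to its longest
    surviving container (ties: lexicographically smallest).
    """
    counts = Counter(sequences)
    keys = list(counts)
    survivors = [
        s for s in keys if not any(s != t and s in t for t in keys)
    ]
    collapsed = {s: counts[s] for s in survivors}
    n_inclusive = 0
    for s in keys:
        if s in collapsed:
            continue
        containers = sorted(
            (t for t in survivors if s in t), key=lambda t: (-len(t), t)
        )
        collapsed[containers[0]] += counts[s]
        n_inclusive += counts[s]
    n_input = sum(counts.values())
    return {
        "uniques": collapsed,
        "n_input": n_input,
        "n_distinct": len(keys),
        "n_inclusive_removed": n_inclusive,
        "n_identical_removed": n_input - n_inclusive - len(survivors),
    }


def depth_oracle(
    records: Sequence, scaffold_lengths: dict[str, int]
) -> tuple[dict[str, list[int]], int]:
    """Per-base depth by walking every record's CIGAR one base at a time."""
    depths = {name: [0] * length for name, length in scaffold_lengths.items()}
    n_mapped = 0
    for rec in records:
        if rec.flag & (0x4 | 0x100 | 0x800) or rec.rname == "*" or rec.cigar == "*":
            continue
        position = rec.pos - 1
        for n, op in _CIGAR.findall(rec.cigar):
            n = int(n)
            if op in "M=X":
                for _ in range(n):
                    depths[rec.rname][position] += 1
                    position += 1
            elif op in "DN":
                position += n
        n_mapped += 1
    return depths, n_mapped


def cross_overlap_oracle(
    seqs_a: Sequence[str], seqs_b: Sequence[str]
) -> tuple[list[bool], list[bool]]:
    """All-pairs identity/containment flags for two unique-sequence sets."""
    flags_a = [any(a in b or b in a for b in seqs_b) for a in seqs_a]
    flags_b = [any(b in a or a in b for a in seqs_a) for b in seqs_b]
    return flags_a, flags_b
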