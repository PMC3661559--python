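"""Exact-match mapping of collapsed small-RNA reads onto precursor
candidates, the expression gate, and the siRNA-exclusion signals.

Reads map sense when they are exact substrings of the candidate and
antisense when their reverse complement is.  Only 18-25-nt reads are
considered.  Two signals separate siRNA-producing loci from miRNA
precursors: the fraction of unique reads on the antisense strand (siRNA
loci exceed 10%) and "continuous" sense coverage, operationalized as the
density of distinct read 5' start positions in a sliding window (a smeared
read distribution indicates imprecise cleavage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, to_dna
from .genome_io import SmallRnaLibrary

MIN_READ_LEN = 18
MAX_READ_LEN = 25


@dataclass(frozen=True)
class MappedRead:
    sequence: str
    count: int
    positions: tuple[tuple[int, int], ...]  # 0-based half-open on the candidate
    strand: str  # "sense" | "antisense"
    n_genome_hits: int = 1


@dataclass
class ReadStack:
    """All reads from a library that map onto one candidate sequence."""

    candidate_id: str
    candidate_length: int
    reads: list[MappedRead] = field(default_factory=list)

    @property
    def sense_reads(self) -> list[MappedRead]:
        return [r for r in self.reads if r.strand == "sense"]

    @property
    def antisense_reads(self) -> list[MappedRead]:
        return [r for r in self.reads if r.strand == "antisense"]

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.reads)

    @property
    def unique_reads(self) -> int:
        return len(self.reads)

    def sense_coverage(self) -> np.ndarray:
        cov = np.zeros(self.candidate_length, dtype=np.int64)
        for r in self.sense_reads:
            for s, e in r.positions:
                cov[s:e] += r.count
        return cov

    def sense_interval_counts(self) -> dict[tuple[int, int], int]:
        """Summed read count per exact sense interval."""
        counts: dict[tuple[int, int], int] = {}
        for r in self.sense_reads:
            for pos in r.positions:
                counts[pos] = counts.get(pos, 0) + r.count
        return counts


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return hits
        hits.append(idx)
        start = idx + 1


def map_reads(
    library: SmallRnaLibrary,
    candidate_sequence: str,
    candidate_id: str = "",
    genome_hits: dict[str, int] | None = None,
    dual_strand: str = "sense_priority",
) -> ReadStack:
    """Exact-substring mapping of a collapsed library onto one candidate.

    On a fold-back locus the reverse complement of a 5'-arm read is often
    itself present on the 3' arm, so a read can match both strands.  The
    default ``sense_priority`` policy attributes such reads to the sense
    strand and counts a read as antisense only when it matches exclusively
    the reverse strand (the signature of a genuine antisense transcript);
    ``dual_strand="both"`` records both placements instead.

    ``genome_hits`` optionally carries the genome-wide hit count per read
    sequence (reported, never used to discount counts).
    """
    cand = to_dna(candidate_sequence)
    stack = ReadStack(candidate_id, len(cand))
    for seq, count in sorted(library.entries.items()):
        if not MIN_READ_LEN <= len(seq) <= MAX_READ_LEN:
            continue
        read_dna = to_dna(seq)
        n_hits = (genome_hits or {}).get(seq, 1)
        sense_pos = _find_all(cand, read_dna)
        if sense_pos:
            stack.reads.append(
                MappedRead(
                    seq,
                    count,
                    tuple((p, p + len(seq)) for p in sense_pos),
                    "sense",
                    n_hits,
                )
            )
        if sense_pos and dual_strand == "sense_priority":
            continue
        anti_pos = _find_all(cand, revcomp(read_dna))
        if anti_pos:
            stack.reads.append(
                MappedRead(
                    seq,
                    count,
                    tuple((p, p + len(seq)) for p in anti_pos),
                    "antisense",
                    n_hits,
                )
            )
    return stack


def expression_gate(stack: ReadStack, min_total: int = 100) -> bool:
    """A candidate is expressed when the summed count of all matched reads
    reaches ``min_total`` (default 100)."""
    return stack.total_reads >= min_total


def antisense_unique_fraction(stack: ReadStack) -> float:
    """Fraction of distinct mapped read sequences on the antisense strand."""
    if stack.unique_reads == 0:
        raise ValueError("antisense fraction undefined for an empty stack")
    return len(stack.antisense_reads) / stack.unique_reads


def is_continuous_coverage(
    stack: ReadStack, window: int = 30, min_distinct_starts: int = 10
) -> bool:
    """True when some sliding window of ``window`` nt contains more than
    ``min_distinct_starts`` distinct sense 5' start positions — the smeared
    read pattern of imprecise (siRNA-like) processing."""
    starts = sorted({s for r in stack.sense_reads for s, _ in r.positions})
    if not starts:
        return False
    left = 0
    for right in range(len(starts)):
        while starts[right] - starts[left] >= window:
            left += 1
        if right - left + 1 > min_distinct_starts:
            return True
    return False
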