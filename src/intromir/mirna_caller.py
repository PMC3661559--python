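"""Mature/star duplex calling on accepted hairpins.

A plant miRNA/miRNA* duplex leaves a characteristic signature: two read
stacks on opposite hairpin arms whose paired region is offset so that each
strand carries a 2-nt 3' overhang.  Given a read stack and the hairpin
pair table, the caller derives the expected star interval for every
observed read position, gates candidates on read support (>20 reads on
either strand), applies the annotation criteria (<=4 mismatches in the
duplex, asymmetric bulges of at most 1-2 nt, at most one bulge), collapses
overlapping candidates, and finally applies the duplex read-ratio gate
(duplex reads must account for >=40% of all reads on the hairpin).
Kilobase-scale hairpins yielding many precise products are flagged as
miRNA-like rather than canonical precursors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hairpin_fold import HairpinStructure
from .srna_mapping import ReadStack


@dataclass(frozen=True)
class DuplexCall:
    precursor_id: str
    mature: tuple[int, int]  # 0-based half-open on the precursor
    mature_sequence: str
    mature_count: int
    star: tuple[int, int]
    star_sequence: str
    star_count: int
    mismatches_in_duplex: int
    bulges: tuple[tuple[str, int], ...]  # (side, size)
    rank: int = 0

    @property
    def star_deficient(self) -> bool:
        return self.star_count == 0

    @property
    def duplex_total_reads(self) -> int:
        return self.mature_count + self.star_count


@dataclass
class PrecursorCall:
    precursor_id: str
    hairpin: HairpinStructure
    duplexes: list[DuplexCall] = field(default_factory=list)
    duplex_read_ratio: float = 0.0
    star_deficient: bool = False
    mirna_like: bool = False

    @property
    def n_products(self) -> int:
        return len(self.duplexes)

    @property
    def mature_sequences(self) -> list[str]:
        return [d.mature_sequence for d in self.duplexes]


# --------------------------------------------------------------------------
# star geometry
# --------------------------------------------------------------------------

def expected_star_interval(
    mature: tuple[int, int], pair_table: np.ndarray
) -> tuple[int, int] | None:
    """Expected miRNA* interval for a mature read at ``mature`` (0-based
    half-open), such that both duplex strands carry 2-nt 3' overhangs:
    the star 5' end is the partner of the mature position 2 nt upstream of
    its 3' end, and the star 3' end extends 2 nt past the partner of the
    mature 5' end.  Returns None when the required partners are unpaired
    (e.g. a read spanning the terminal loop) or out of range."""
    s, e = mature
    n = len(pair_table)
    if e - s < 4 or s < 0 or e > n:
        return None
    anchor_3p = e - 3  # last mature position that should sit in the duplex
    if pair_table[anchor_3p] < 0 or pair_table[s] < 0:
        return None
    star_start = int(pair_table[anchor_3p])
    star_end = int(pair_table[s]) + 3  # +2 overhang, +1 half-open
    if not (0 <= star_start < star_end <= n):
        return None
    if star_start < e and s < star_end:
        # overlapping mature/star means the read runs through the terminal
        # loop rather than sitting on one arm
        return None
    return star_start, star_end


def duplex_defects(
    mature: tuple[int, int],
    star: tuple[int, int],
    pair_table: np.ndarray,
) -> tuple[int, tuple[tuple[str, int], ...]]:
    """Count mismatches (opposing unpaired positions) and bulges (unopposed
    positions) inside the duplex region, excluding the 2-nt 3' overhangs.

    The walk follows the mature strand 5'->3'; runs of unpaired mature
    positions are compared with the simultaneous jump on the star strand:
    the symmetric part of a loop counts as mismatches, the asymmetric
    excess as one bulge on the longer side.
    """
    s, e = mature
    star_lo, star_hi = star[0], star[1] - 2  # star pairing core
    mismatches = 0
    bulges: list[tuple[str, int]] = []
    prev_partner: int | None = None
    run = 0

    def close_run(run: int, star_gap: int) -> None:
        nonlocal mismatches
        sym = min(run, star_gap)
        mismatches += sym
        if run > star_gap:
            bulges.append(("mature", run - star_gap))
        elif star_gap > run:
            bulges.append(("star", star_gap - run))

    for i in range(s, e - 2):  # mature pairing core
        p = int(pair_table[i])
        if p < 0 or not (star_lo <= p < star_hi):
            run += 1
            continue
        star_gap = (prev_partner - p - 1) if prev_partner is not None else 0
        if run or star_gap:
            close_run(run, star_gap)
        run = 0
        prev_partner = p
    if run:  # trailing unpaired mature positions: opposing star side unknown
        mismatches += run
    return mismatches, tuple(bulges)


# --------------------------------------------------------------------------
# calling
# --------------------------------------------------------------------------

def call_duplexes(
    stack: ReadStack,
    hairpin: HairpinStructure,
    min_reads: int = 20,
    max_mismatches: int = 4,
    max_bulge_size: int = 2,
    max_bulges: int = 1,
    star_jitter: int = 0,
    allow_star_deficient: bool = True,
    precursor_id: str | None = None,
) -> list[DuplexCall]:
    """Rank observed sense read positions, pair each with its expected star
    position, and retain duplexes passing the read-support gate and the
    annotation criteria.  Reciprocal duplicates (mature/star swapped) and
    overlapping candidates are collapsed to the highest-count representative.
    """
    pid = precursor_id if precursor_id is not None else stack.candidate_id
    pt = hairpin.pair_table
    seq = hairpin.sequence
    interval_counts = stack.sense_interval_counts()

    candidates: list[DuplexCall] = []
    for mature_iv, count in sorted(
        interval_counts.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        star_iv = expected_star_interval(mature_iv, pt)
        if star_iv is None:
            continue
        star_count = _observed_count(interval_counts, star_iv, star_jitter)
        if not (count > min_reads or star_count > min_reads):
            continue
        if star_count == 0 and not allow_star_deficient:
            continue
        mism, bulges = duplex_defects(mature_iv, star_iv, pt)
        if mism > max_mismatches:
            continue
        if len(bulges) > max_bulges or any(b[1] > max_bulge_size for b in bulges):
            continue
        candidates.append(
            DuplexCall(
                pid,
                mature_iv,
                seq[mature_iv[0] : mature_iv[1]],
                count,
                star_iv,
                seq[star_iv[0] : star_iv[1]],
                star_count,
                mism,
                bulges,
            )
        )

    accepted: list[DuplexCall] = []
    for cand in sorted(
        candidates, key=lambda d: (-d.duplex_total_reads, d.mature)
    ):
        if any(_same_duplex(cand, kept) for kept in accepted):
            continue
        if any(_intervals_overlap(cand.mature, kept.mature) for kept in accepted):
            continue
        accepted.append(cand)
    return [
        DuplexCall(
            d.precursor_id, d.mature, d.mature_sequence, d.mature_count,
            d.star, d.star_sequence, d.star_count, d.mismatches_in_duplex,
            d.bulges, rank=i + 1,
        )
        for i, d in enumerate(accepted)
    ]


def _observed_count(
    interval_counts: dict[tuple[int, int], int],
    interval: tuple[int, int],
    jitter: int,
) -> int:
    if jitter == 0:
        return interval_counts.get(interval, 0)
    best = 0
    for (s, e), c in interval_counts.items():
        if abs(s - interval[0]) <= jitter and abs(e - interval[1]) <= jitter:
            best = max(best, c)
    return best


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _same_duplex(a: DuplexCall, b: DuplexCall) -> bool:
    """a and b describe one physical duplex if a's mature sits where b's
    star is expected and vice versa (allowing the 2-nt overhang shift)."""
    return _intervals_overlap(a.mature, b.star) and _intervals_overlap(
        a.star, b.mature
    )


def duplex_read_ratio(stack: ReadStack, duplexes: list[DuplexCall]) -> float:
    """Fraction of all stack reads (by count) lying inside the accepted
    mature+star intervals."""
    if stack.total_reads == 0:
        raise ValueError("duplex read ratio undefined for an empty stack")
    regions = [d.mature for d in duplexes] + [d.star for d in duplexes]
    in_duplex = 0
    for read in stack.sense_reads:
        for pos in read.positions:
            if any(r[0] <= pos[0] and pos[1] <= r[1] for r in regions):
                in_duplex += read.count
                break
    return in_duplex / stack.total_reads


def duplex_read_ratio_gate(ratio: float, min_ratio: float = 0.40) -> bool:
    return ratio >= min_ratio


def flag_mirna_like(
    hairpin_length: int,
    n_products: int,
    min_len: int = 1000,
    min_products: int = 8,
) -> bool:
    """Kilobase-scale hairpins producing many distinct precise small RNAs
    are miRNA-like long hairpins rather than canonical precursors."""
    return hairpin_length >= min_len and n_products >= min_products


def call_precursor(
    stack: ReadStack,
    hairpin: HairpinStructure,
    precursor_id: str | None = None,
    min_reads: int = 20,
    min_ratio: float = 0.40,
    mirna_like_min_len: int = 1000,
    mirna_like_min_products: int = 8,
    **caller_kwargs,
) -> PrecursorCall | None:
    """Full per-precursor calling: duplexes, ratio gate, miRNA-like flag.
    Returns None when no duplex passes or the ratio gate fails (unless the
    locus qualifies as a miRNA-like long hairpin)."""
    pid = precursor_id if precursor_id is not None else stack.candidate_id
    duplexes = call_duplexes(
        stack, hairpin, min_reads=min_reads, precursor_id=pid, **caller_kwargs
    )
    if not duplexes:
        return None
    ratio = duplex_read_ratio(stack, duplexes)
    mirna_like = flag_mirna_like(
        len(hairpin), len(duplexes), mirna_like_min_len, mirna_like_min_products
    )
    if not duplex_read_ratio_gate(ratio, min_ratio) and not mirna_like:
        return None
    return PrecursorCall(
        pid,
        hairpin,
        duplexes,
        ratio,
        star_deficient=any(d.star_deficient for d in duplexes),
        mirna_like=mirna_like,
    )
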