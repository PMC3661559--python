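"""Inverted-repeat (fold-back) detection inside intron sequences.

Each intron is locally aligned against its own reverse complement with an
ungapped seed-and-extend strategy (BLASTN-like: 11-nt exact seeds, X-drop
extension, minimum identity).  Hits are clustered into candidate fragments;
a fragment is accepted as an inverted repeat when its span exceeds 50 nt
and the union of hit footprints covers at least 30% of the span.  Among
IRs that overlap the same genomic locus only the longest is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import check_alphabet, revcomp, to_dna


@dataclass(frozen=True)
class SelfAlignmentHit:
    """An ungapped pairing of two sub-sequences of one intron that are
    (approximate) reverse complements.  Both intervals are 0-based half-open
    forward-strand coordinates on the intron; ``query`` starts left of or at
    ``subject`` (canonical orientation, deduplicated)."""

    query: tuple[int, int]
    subject: tuple[int, int]
    length: int
    identity: float

    def footprint(self) -> list[tuple[int, int]]:
        return [self.query, self.subject]


@dataclass(frozen=True)
class InvertedRepeat:
    """A candidate fold-back locus within an intron."""

    intron_id: str
    start: int  # within-intron, 0-based half-open
    end: int
    hit_coverage: float
    sequence: str
    chrom: str = ""
    genomic_start: int = -1  # on the chromosome, if known
    genomic_end: int = -1

    @property
    def span(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.span


# --------------------------------------------------------------------------
# seed-and-extend self alignment
# --------------------------------------------------------------------------

_MATCH_SCORE = 1
_MISMATCH_SCORE = -2
_XDROP = 6


def _extend_ungapped(
    s: str, r: str, q0: int, t0: int, seed_len: int
) -> tuple[int, int, int]:
    """Extend an exact seed match s[q0:q0+seed_len] == r[t0:t0+seed_len]
    on both sides with X-drop; returns (q_start, t_start, length) of the
    maximum-scoring ungapped extension."""
    n = len(s)
    # right extension
    best_right = 0
    score = 0
    best_score = 0
    i = q0 + seed_len
    j = t0 + seed_len
    while i < n and j < n:
        score += _MATCH_SCORE if s[i] == r[j] else _MISMATCH_SCORE
        if score > best_score:
            best_score = score
            best_right = i - (q0 + seed_len) + 1
        if best_score - score > _XDROP:
            break
        i += 1
        j += 1
    # left extension
    best_left = 0
    score = 0
    best_score = 0
    i = q0 - 1
    j = t0 - 1
    while i >= 0 and j >= 0:
        score += _MATCH_SCORE if s[i] == r[j] else _MISMATCH_SCORE
        if score > best_score:
            best_score = score
            best_left = q0 - i
        if best_score - score > _XDROP:
            break
        i -= 1
        j -= 1
    return q0 - best_left, t0 - best_left, seed_len + best_left + best_right


def _hit_from_extension(
    s: str, r: str, q: int, t: int, length: int, min_identity: float
) -> SelfAlignmentHit | None:
    n = len(s)
    matches = sum(1 for k in range(length) if s[q + k] == r[t + k])
    identity = matches / length
    if identity < min_identity:
        return None
    # map the subject interval on revcomp(s) back to forward coordinates
    sub = (n - (t + length), n - t)
    qiv = (q, q + length)
    a, b = sorted([qiv, sub])
    return SelfAlignmentHit(a, b, length, identity)


def self_align_revcomp(
    sequence: str, seed_len: int = 11, min_identity: float = 0.8
) -> list[SelfAlignmentHit]:
    """Align an intron against its own reverse complement.

    Returns deduplicated, canonically oriented ungapped hits: every hit
    pairs two sub-sequences of the intron that are reverse complements of
    each other up to ``min_identity``.
    """
    s = to_dna(sequence)
    check_alphabet(s, "intron sequence")
    n = len(s)
    if n < 2 * seed_len:
        raise ValueError(f"sequence length {n} < 2 x seed length {seed_len}")
    r = revcomp(s)
    index: dict[str, list[int]] = {}
    for t in range(n - seed_len + 1):
        word = r[t : t + seed_len]
        if "N" in word:
            continue
        index.setdefault(word, []).append(t)
    hits: set[SelfAlignmentHit] = set()
    for q in range(n - seed_len + 1):
        word = s[q : q + seed_len]
        if "N" in word:
            continue
        for t in index.get(word, ()):
            eq, et, length = _extend_ungapped(s, r, q, t, seed_len)
            hit = _hit_from_extension(s, r, eq, et, length, min_identity)
            if hit is not None:
                hits.add(hit)
    return sorted(hits, key=lambda h: (h.query, h.subject))


# --------------------------------------------------------------------------
# clustering and acceptance
# --------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        if start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def cluster_hits_to_irs(
    hits: list[SelfAlignmentHit],
    intron_id: str = "",
    sequence: str | None = None,
    min_len: int = 50,
    min_cov: float = 0.30,
    join_gap: int = 15,
) -> list[InvertedRepeat]:
    """Merge hit footprints within ``join_gap`` of each other into fragments
    and accept a fragment as an IR iff span > min_len (strict) and the union
    of hit footprints covers >= min_cov of the span."""
    if not hits:
        return []
    footprints: list[tuple[int, int]] = []
    for h in hits:
        footprints.extend(h.footprint())
    footprints.sort()
    # single-linkage merge along the intron
    fragments: list[list[tuple[int, int]]] = [[footprints[0]]]
    frag_end = footprints[0][1]
    for iv in footprints[1:]:
        if iv[0] <= frag_end + join_gap:
            fragments[-1].append(iv)
            frag_end = max(frag_end, iv[1])
        else:
            fragments.append([iv])
            frag_end = iv[1]
    irs = []
    for members in fragments:
        start = min(iv[0] for iv in members)
        end = max(iv[1] for iv in members)
        span = end - start
        coverage = _union_length(members) / span
        if span > min_len and coverage >= min_cov:
            seq = sequence[start:end] if sequence is not None else ""
            irs.append(InvertedRepeat(intron_id, start, end, coverage, seq))
    return irs


def with_genomic_coords(ir: InvertedRepeat, intron) -> InvertedRepeat:
    """Attach chromosome coordinates to an intron-relative IR.  For minus
    strand introns the intron-relative axis runs against genomic order."""
    if intron.strand == "+":
        g0 = intron.start + ir.start
        g1 = intron.start + ir.end
    else:
        g0 = intron.end - ir.end
        g1 = intron.end - ir.start
    return InvertedRepeat(
        ir.intron_id, ir.start, ir.end, ir.hit_coverage, ir.sequence,
        intron.chrom, g0, g1,
    )


def dedupe_irs(irs: list[InvertedRepeat]) -> list[InvertedRepeat]:
    """Among IRs whose genomic spans overlap (same chromosome), keep only the
    longest; ties broken by leftmost genomic start, then lexicographic
    intron id."""
    if any(ir.genomic_start < 0 for ir in irs):
        raise ValueError("dedupe_irs requires genomic coordinates on every IR")
    remaining = sorted(irs, key=lambda ir: (ir.chrom, ir.genomic_start, ir.genomic_end))
    kept: list[InvertedRepeat] = []
    # connected components of genomic overlap, per chromosome
    component: list[InvertedRepeat] = []
    comp_end = None
    comp_chrom = None
    for ir in remaining:
        if component and ir.chrom == comp_chrom and ir.genomic_start < comp_end:
            component.append(ir)
            comp_end = max(comp_end, ir.genomic_end)
        else:
            if component:
                kept.append(_pick_longest(component))
            component = [ir]
            comp_end = ir.genomic_end
            comp_chrom = ir.chrom
    if component:
        kept.append(_pick_longest(component))
    return kept


def _pick_longest(component: list[InvertedRepeat]) -> InvertedRepeat:
    return min(
        component, key=lambda ir: (-ir.span, ir.genomic_start, ir.intron_id)
    )
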