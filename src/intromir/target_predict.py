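"""miRNA target prediction with a complementarity penalty score.

The miRNA (5'->3') is aligned against candidate sites in antiparallel
orientation and penalized per column: a mismatch costs 1, a G:U wobble
0.5, and a bulge (unpaired nucleotide on either strand) 2.  A site passes
when the total score is at most 2.5, at least one of miRNA positions 10
and 11 (the cleavage site) is a Watson-Crick match, and positions 2-9
(the seed) carry at most one non-match event.  Sites can be scanned on
transcripts (mRNA cleavage targets) or on both genomic strands (DNA-level
targets of 24-nt methylation-guiding miRNAs), with flags marking sites in
the miRNA's own host gene or overlapping its own precursor locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, to_rna

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

# doubled-integer penalties to keep the DP exact
_MATCH = 0
_WOBBLE = 1
_MISMATCH = 2
_BULGE = 4


@dataclass(frozen=True)
class AlignmentColumn:
    mirna_pos: int | None  # 1-based from the miRNA 5' end; None for site bulges
    site_pos: int | None  # 0-based on the site window; None for miRNA bulges
    kind: str  # match | wobble | mismatch | bulge_mirna | bulge_site


@dataclass(frozen=True)
class TargetAlignment:
    mirna: str
    site: str  # the genomic/transcript window, 5'->3'
    columns: tuple[AlignmentColumn, ...]
    score: float

    @property
    def n_bulges(self) -> int:
        return sum(1 for c in self.columns if c.kind.startswith("bulge"))

    def kinds_by_position(self) -> dict[int, str]:
        return {c.mirna_pos: c.kind for c in self.columns if c.mirna_pos is not None}


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    gene_id: str
    start: int  # site interval on the gene sequence, 0-based half-open
    end: int
    strand: str
    alignment: TargetAlignment
    passes: bool
    reasons: tuple[str, ...]
    self_target: bool = False
    own_locus: bool = False

    @property
    def score(self) -> float:
        return self.alignment.score


_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _encode(rna: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in rna], dtype=np.int8)


@njit(cache=True)
def _dp_score_doubled(m, r):  # pragma: no cover - numba
    """Minimum doubled penalty of the global alignment (score only); used
    as a fast exact filter before the full column-producing alignment."""
    nm, ns = m.shape[0], r.shape[0]
    big = 1 << 20
    dp = np.full((nm + 1, ns + 1), big, dtype=np.int32)
    dp[0, 0] = 0
    for i in range(nm + 1):
        for j in range(ns + 1):
            v = dp[i, j]
            if v >= big:
                continue
            if i < nm and j < ns:
                a, b = m[i], r[j]
                if a == b and a < 4:
                    cost = 0
                elif (a == 2 and b == 0) or (a == 3 and b == 1):
                    cost = 1  # G:U wobble
                else:
                    cost = 2
                if v + cost < dp[i + 1, j + 1]:
                    dp[i + 1, j + 1] = v + cost
            if j < ns and v + 4 < dp[i, j + 1]:
                dp[i, j + 1] = v + 4
            if i < nm and v + 4 < dp[i + 1, j]:
                dp[i + 1, j] = v + 4
    return dp[nm, ns]


def _column_kind(m_base: str, rc_base: str) -> str:
    """Pairing class for miRNA base vs the reverse-complemented site base.
    In this frame equality means a Watson-Crick pair; G:U wobbles appear
    as (G,A) or (U,C)."""
    if m_base == rc_base:
        return "match"
    if (m_base, rc_base) in (("G", "A"), ("U", "C")):
        return "wobble"
    return "mismatch"


def align_target(mirna: str, site_window: str) -> TargetAlignment:
    """Minimum-penalty global alignment of the miRNA against the site
    window in antiparallel orientation.

    Ties are broken toward fewer bulges, then toward pairing columns
    early (leftmost from the miRNA 5' end).
    """
    m = to_rna(mirna)
    site = site_window.upper()
    rc = to_rna(revcomp(site))
    nm, ns = len(m), len(rc)
    if ns < nm - 2:
        raise ValueError(
            "site window shorter than the miRNA minus the allowed bulges"
        )
    INF = (1 << 30, 1 << 30)
    # dp[i][j] = (doubled score, n_bulges) aligning m[:i] with rc[:j]
    dp = [[INF] * (ns + 1) for _ in range(nm + 1)]
    back = [[None] * (ns + 1) for _ in range(nm + 1)]
    dp[0][0] = (0, 0)
    for i in range(nm + 1):
        for j in range(ns + 1):
            if dp[i][j] == INF:
                continue
            score, nb = dp[i][j]
            if i < nm and j < ns:  # pair column
                kind = _column_kind(m[i], rc[j])
                cost = {"match": _MATCH, "wobble": _WOBBLE, "mismatch": _MISMATCH}[kind]
                cand = (score + cost, nb)
                if cand < dp[i + 1][j + 1]:
                    dp[i + 1][j + 1] = cand
                    back[i + 1][j + 1] = ("pair", kind)
            if j < ns:  # unpaired site base (bulge on the site strand)
                cand = (score + _BULGE, nb + 1)
                if cand < dp[i][j + 1]:
                    dp[i][j + 1] = cand
                    back[i][j + 1] = ("bulge_site", None)
            if i < nm:  # unpaired miRNA base
                cand = (score + _BULGE, nb + 1)
                if cand < dp[i + 1][j]:
                    dp[i + 1][j] = cand
                    back[i + 1][j] = ("bulge_mirna", None)
    i, j = nm, ns
    rev_cols: list[AlignmentColumn] = []
    while i > 0 or j > 0:
        move = back[i][j]
        if move is None:
            raise RuntimeError("alignment traceback failed")
        if move[0] == "pair":
            i -= 1
            j -= 1
            rev_cols.append(AlignmentColumn(i + 1, ns - 1 - j, move[1]))
        elif move[0] == "bulge_site":
            j -= 1
            rev_cols.append(AlignmentColumn(None, ns - 1 - j, "bulge_site"))
        else:
            i -= 1
            rev_cols.append(AlignmentColumn(i + 1, None, "bulge_mirna"))
    rev_cols.reverse()
    return TargetAlignment(m, site, tuple(rev_cols), dp[nm][ns][0] / 2)


def passes_rules(
    alignment: TargetAlignment,
    max_score: float = 2.5,
    cleavage_mode: str = "or",
    seed_counts_wobble: bool = True,
    max_seed_events: int = 1,
) -> tuple[bool, tuple[str, ...]]:
    """Apply the target-site acceptance rules; returns (passes, reasons)."""
    reasons: list[str] = []
    if alignment.score > max_score:
        reasons.append(f"score {alignment.score:g} exceeds {max_score:g}")
    by_pos = alignment.kinds_by_position()
    cleave = [by_pos.get(10), by_pos.get(11)]
    matches = [k == "match" for k in cleave]
    if cleavage_mode == "both":
        ok = all(matches)
    else:
        ok = any(matches)
    if not ok:
        reasons.append("no perfect match at the position 10/11 cleavage site")
    events = 0
    for col in alignment.columns:
        if col.kind == "match":
            continue
        if col.kind == "wobble" and not seed_counts_wobble:
            continue
        if col.mirna_pos is not None:
            touches = 2 <= col.mirna_pos <= 9
        else:
            # a site bulge sits between two miRNA positions: locate it
            touches = _site_bulge_touches_seed(alignment, col)
        if touches:
            events += 1
    if events > max_seed_events:
        reasons.append(
            f"{events} mismatch/wobble/bulge events in positions 2-9 "
            f"(allowed {max_seed_events})"
        )
    return not reasons, tuple(reasons)


def _site_bulge_touches_seed(alignment: TargetAlignment, col: AlignmentColumn) -> bool:
    idx = alignment.columns.index(col)
    prev_pos = next(
        (c.mirna_pos for c in reversed(alignment.columns[:idx]) if c.mirna_pos),
        0,
    )
    next_pos = next(
        (c.mirna_pos for c in alignment.columns[idx + 1 :] if c.mirna_pos),
        len(alignment.mirna) + 1,
    )
    return (2 <= prev_pos <= 9) or (2 <= next_pos <= 9)


def scan_targets(
    mirna: str,
    sequences: dict[str, str],
    mirna_id: str = "",
    include_dna_level: bool = False,
    host_gene: str | None = None,
    precursor_locus: tuple[str, int, int] | None = None,
    max_score: float = 2.5,
    cleavage_mode: str = "or",
    max_site_bulge: int = 1,
) -> list[TargetHit]:
    """Score every window of each target sequence against the miRNA and
    report sites passing the rules.

    With ``include_dna_level`` both strands of each sequence are scanned
    (DNA-level targeting).  Overlapping passing windows are collapsed to
    the best-scoring (then leftmost) representative per gene and strand.
    ``precursor_locus`` = (gene_id, start, end) marks the miRNA's own
    locus; a passing site overlapping it gets ``own_locus=True``.
    """
    m = to_rna(mirna)
    nm = len(m)
    hits: list[TargetHit] = []
    for gene_id in sorted(sequences):
        seq = sequences[gene_id].upper()
        strands = [("+", seq)]
        if include_dna_level:
            strands.append(("-", revcomp(seq)))
        for strand, s in strands:
            raw: list[TargetHit] = []
            rc_strand = _encode(to_rna(revcomp(s)))
            m_codes = _encode(m)
            ns = len(s)
            for wlen in range(nm - max_site_bulge, nm + max_site_bulge + 1):
                for start in range(0, ns - wlen + 1):
                    window = s[start : start + wlen]
                    # rc of window == slice of rc(strand)
                    rc_win = rc_strand[ns - start - wlen : ns - start]
                    if _dp_score_doubled(m_codes, rc_win) > 2 * max_score:
                        continue
                    aln = align_target(m, window)
                    if aln.score > max_score:
                        continue
                    ok, reasons = passes_rules(aln, max_score, cleavage_mode)
                    if not ok:
                        continue
                    if strand == "+":
                        g0, g1 = start, start + wlen
                    else:
                        g0, g1 = len(s) - start - wlen, len(s) - start
                    own = (
                        precursor_locus is not None
                        and gene_id == precursor_locus[0]
                        and g0 < precursor_locus[2]
                        and precursor_locus[1] < g1
                    )
                    raw.append(
                        TargetHit(
                            mirna_id, gene_id, g0, g1, strand, aln, True, reasons,
                            self_target=(host_gene is not None and gene_id == host_gene),
                            own_locus=own,
                        )
                    )
            hits.extend(_collapse_overlaps(raw))
    return sorted(hits, key=lambda h: (h.gene_id, h.strand, h.start))


def _collapse_overlaps(hits: list[TargetHit]) -> list[TargetHit]:
    kept: list[TargetHit] = []
    for hit in sorted(hits, key=lambda h: (h.score, h.start, h.end)):
        if any(hit.start < k.end and k.start < hit.end for k in kept):
            continue
        kept.append(hit)
    return kept
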