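"""Inverted-repeat detection: seed-and-extend self-alignment, fragment
clustering, and genomic deduplication."""

import numpy as np
import pytest

from intromir._seq import revcomp
from intromir.ir_finder import (
    InvertedRepeat,
    SelfAlignmentHit,
    _extend_ungapped,
    _hit_from_extension,
    cluster_hits_to_irs,
    dedupe_irs,
    self_align_revcomp,
    with_genomic_coords,
)
from intromir.genome_io import Intron

from conftest import random_dna


def oracle_self_align(seq, seed_len=11, min_identity=0.8):
    """Independent seed-and-extend: enumerate ALL k-mer matches between the
    sequence and its reverse complement by direct O(n^2) comparison, extend
    each without gaps, and deduplicate."""
    s = seq.upper()
    r = revcomp(s)
    n = len(s)
    hits = set()
    for q in range(n - seed_len + 1):
        for t in range(n - seed_len + 1):
            if s[q : q + seed_len] != r[t : t + seed_len]:
                continue
            eq, et, length = _extend_ungapped(s, r, q, t, seed_len)
            hit = _hit_from_extension(s, r, eq, et, length, min_identity)
            if hit is not None:
                hits.add(hit)
    return hits


class TestSelfAlign:
    def test_poly_a_has_no_complementarity(self):
        assert self_align_revcomp("A" * 200) == []

    def test_planted_palindrome_pairs_the_two_arms(self, rng):
        x = random_dna(rng, 40)
        seq = x + "A" * 10 + revcomp(x)
        hits = self_align_revcomp(seq)
        assert len(hits) >= 1
        best = max(hits, key=lambda h: h.length)
        assert best.query[0] <= 0 + 2 and best.query[1] >= 38
        assert best.subject[0] <= 52 and best.subject[1] >= 88
        assert best.identity == 1.0

    def test_matches_exhaustive_oracle_on_planted_stem(self, rng):
        stem = random_dna(rng, 60)
        seq = (
            random_dna(rng, 400)
            + stem
            + random_dna(rng, 30)
            + revcomp(stem)
            + random_dna(rng, 400)
        )
        assert set(self_align_revcomp(seq)) == oracle_self_align(seq)

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            self_align_revcomp("ACGTX" * 20)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            self_align_revcomp("ACGTACGTACGTACGT", seed_len=11)


class TestClusterToIrs:
    def test_strong_hit_accepted_with_coverage(self):
        # one hit pairing (0,40) with (50,90): fragment 0..90, 80 nt of hits
        hit = SelfAlignmentHit((0, 40), (50, 90), 40, 1.0)
        (ir,) = cluster_hits_to_irs([hit], "i1", "A" * 90)
        assert ir.span == 90
        assert ir.hit_coverage == pytest.approx(80 / 90)

    def test_low_coverage_fragment_rejected(self):
        hit = SelfAlignmentHit((0, 20), (180, 200), 20, 1.0)
        assert cluster_hits_to_irs([hit], join_gap=300) == []

    def test_span_of_exactly_50_rejected(self):
        # "more than 50 nt" is strict
        hit = SelfAlignmentHit((0, 24), (26, 50), 24, 1.0)
        assert cluster_hits_to_irs([hit]) == []
        hit51 = SelfAlignmentHit((0, 25), (26, 51), 25, 1.0)
        assert len(cluster_hits_to_irs([hit51])) == 1

    def test_empty_in_empty_out(self):
        assert cluster_hits_to_irs([]) == []


def _ir(intron_id, g0, g1):
    return InvertedRepeat(intron_id, 0, g1 - g0, 1.0, "", "chr1", g0, g1)


class TestDedupe:
    def test_longest_of_overlapping_pair_survives(self):
        survivors = dedupe_irs([_ir("a", 0, 120), _ir("b", 50, 140)])
        assert [s.intron_id for s in survivors] == ["a"]

    def test_disjoint_irs_both_survive(self):
        survivors = dedupe_irs([_ir("a", 0, 100), _ir("b", 200, 300)])
        assert len(survivors) == 2

    def test_tie_breaks_by_leftmost_then_id(self):
        irs = [_ir("c", 20, 120), _ir("a", 0, 100), _ir("b", 10, 90)]
        # exhaustive-comparison oracle: among mutually overlapping IRs the
        # max length is 100, achieved by 'a' (leftmost) and 'c'
        lengths = [(ir.span, ir.genomic_start, ir.intron_id) for ir in irs]
        expected = min(lengths, key=lambda t: (-t[0], t[1], t[2]))[2]
        survivors = dedupe_irs(irs)
        assert [s.intron_id for s in survivors] == [expected] == ["a"]


class TestInvariantsOnPlantedStem:
    def _intron_with_stem(self, rng, mismatches=0):
        stem = list(random_dna(rng, 70))
        arm2 = list(revcomp("".join(stem)))
        for k in rng.choice(50, size=mismatches, replace=False):
            arm2[10 + k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm2[10 + k]]
        seq = random_dna(rng, 100) + "".join(stem) + "TTTAGC" + "".join(arm2) + random_dna(rng, 100)
        return seq

    def test_ir_within_intron_and_coverage_recomputable(self, rng):
        seq = self._intron_with_stem(rng, mismatches=4)
        hits = self_align_revcomp(seq)
        for ir in cluster_hits_to_irs(hits, "i1", seq):
            assert 0 <= ir.start < ir.end <= len(seq)
            footprints = []
            for h in hits:
                for iv in h.footprint():
                    if ir.start <= iv[0] and iv[1] <= ir.end:
                        footprints.append(iv)
            union = _union_len(footprints)
            assert ir.hit_coverage == pytest.approx(union / ir.span, abs=1e-9)

    def test_revcomp_of_intron_mirrors_ir_spans(self, rng):
        seq = self._intron_with_stem(rng)
        irs_fwd = cluster_hits_to_irs(self_align_revcomp(seq), "i", seq)
        rc = revcomp(seq)
        irs_rev = cluster_hits_to_irs(self_align_revcomp(rc), "i", rc)
        n = len(seq)
        mirrored = sorted((n - ir.end, n - ir.start) for ir in irs_rev)
        assert mirrored == sorted((ir.start, ir.end) for ir in irs_fwd)

    def test_recall_on_planted_stems_with_mismatch(self, rng):
        found = 0
        trials = 20
        for _ in range(trials):
            seq = self._intron_with_stem(rng, mismatches=6)  # <10% of 70
            irs = cluster_hits_to_irs(self_align_revcomp(seq), "i1", seq)
            found += any(
                ir.start <= 110 and ir.end >= 100 + 70 + 6 + 60 for ir in irs
            )
        assert found == trials

    def test_genomic_mapping_minus_strand(self, rng):
        seq = self._intron_with_stem(rng)
        intron = Intron("g", "chr1", "-", 1000, 1000 + len(seq), 1, seq)
        (ir,) = cluster_hits_to_irs(self_align_revcomp(seq), intron.intron_id, seq)
        g = with_genomic_coords(ir, intron)
        assert g.genomic_end - g.genomic_start == ir.span
        # intron-relative start measured from the transcript 5' end maps to
        # the genomic right edge for a minus-strand intron
        assert g.genomic_end == intron.end - ir.start


def _union_len(intervals):
    total, last = 0, -1
    for s, e in sorted(intervals):
        if s > last:
            total += e - s
            last = e
        elif e > last:
            total += e - last
            last = e
    return total
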