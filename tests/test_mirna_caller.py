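"""Duplex geometry, annotation-criteria gating, the 40% read-ratio rule and
the miRNA-like long-hairpin flag."""

import numpy as np
import pytest

from intromir._seq import revcomp
from intromir.genome_io import SmallRnaLibrary
from intromir.hairpin_fold import fold
from intromir.mirna_caller import (
    call_duplexes,
    duplex_defects,
    duplex_read_ratio,
    duplex_read_ratio_gate,
    expected_star_interval,
    flag_mirna_like,
)
from intromir.srna_mapping import map_reads

from conftest import random_dna


def perfect_pair_table(n, stem, loop):
    """Pair table of an ideal hairpin pairing i <-> n-1-i outside the loop."""
    pt = np.full(n, -1, dtype=np.int64)
    for i in range(stem):
        pt[i] = n - 1 - i
        pt[n - 1 - i] = i
    return pt


class TestExpectedStar:
    # 70-nt hairpin, stem 30 bp, loop 10: 1-based pairing i <-> 71-i
    pt = perfect_pair_table(70, 30, 10)

    def test_mature_on_5prime_arm(self):
        # 1-based mature (3,23) -> 0-based [2,23); manual pair-table oracle:
        # star 5' = partner(21) = 50, star 3' = partner(3)+2 = 70 (1-based)
        assert expected_star_interval((2, 23), self.pt) == (49, 70)

    def test_mature_spanning_the_loop_has_no_star(self):
        assert expected_star_interval((27, 48), self.pt) is None

    def test_involution_from_3prime_arm(self):
        # the star of the star is the original mature
        assert expected_star_interval((49, 70), self.pt) == (2, 23)


@pytest.fixture()
def hairpin_with_reads(rng):
    arm = random_dna(rng, 60)
    seq = arm + "CAACATTC" + revcomp(arm)
    hairpin = fold(seq)
    n = len(seq)
    mature = seq[4:25]
    star = seq[n + 2 - 25 : n + 2 - 4]
    return seq, hairpin, mature, star


class TestCallDuplexes:
    def test_star_deficient_call_retained(self, hairpin_with_reads):
        seq, hairpin, mature, _ = hairpin_with_reads
        stack = map_reads(SmallRnaLibrary("s", {mature: 21}), seq)
        calls = call_duplexes(stack, hairpin)
        assert len(calls) == 1
        assert calls[0].star_deficient
        assert calls[0].mature_sequence == mature.replace("T", "U")

    def test_star_deficient_dropped_when_disallowed(self, hairpin_with_reads):
        seq, hairpin, mature, _ = hairpin_with_reads
        stack = map_reads(SmallRnaLibrary("s", {mature: 21}), seq)
        assert call_duplexes(stack, hairpin, allow_star_deficient=False) == []

    def test_low_support_on_both_strands_dropped(self, hairpin_with_reads):
        seq, hairpin, mature, star = hairpin_with_reads
        stack = map_reads(SmallRnaLibrary("s", {mature: 5, star: 5}), seq)
        assert call_duplexes(stack, hairpin) == []

    def test_star_above_threshold_rescues_weak_mature(self, hairpin_with_reads):
        seq, hairpin, mature, star = hairpin_with_reads
        stack = map_reads(SmallRnaLibrary("s", {mature: 5, star: 25}), seq)
        calls = call_duplexes(stack, hairpin)
        assert len(calls) == 1

    def test_duplex_with_five_mismatches_rejected(self, rng):
        arm = random_dna(rng, 60)
        arm2 = list(revcomp(arm))
        # engineer 5 mismatches opposite the mature core [4,22)
        for k in range(5):
            pos = 120 + 8 - 1 - (6 + 2 * k)  # partner of mature position 6+2k
            idx = pos - 68
            arm2[idx] = arm[6 + 2 * k]  # same base cannot pair its complement
        seq = arm + "CAACATTC" + "".join(arm2)
        hairpin = fold(seq)
        mature = seq[4:25]
        stack = map_reads(SmallRnaLibrary("s", {mature: 50}), seq)
        assert call_duplexes(stack, hairpin) == []

    def test_reciprocal_duplex_reported_once(self, hairpin_with_reads):
        seq, hairpin, mature, star = hairpin_with_reads
        stack = map_reads(SmallRnaLibrary("s", {mature: 100, star: 40}), seq)
        calls = call_duplexes(stack, hairpin)
        assert len(calls) == 1
        assert calls[0].mature_count == 100
        assert calls[0].star_count == 40

    def test_raising_min_reads_never_increases_calls(self, hairpin_with_reads):
        seq, hairpin, mature, star = hairpin_with_reads
        stack = map_reads(SmallRnaLibrary("s", {mature: 100, star: 40}), seq)
        counts = [
            len(call_duplexes(stack, hairpin, min_reads=m)) for m in (5, 20, 50, 150)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_overhang_geometry_on_accepted_duplex(self, hairpin_with_reads):
        seq, hairpin, mature, star = hairpin_with_reads
        stack = map_reads(SmallRnaLibrary("s", {mature: 100, star: 40}), seq)
        (call,) = call_duplexes(stack, hairpin)
        pt = hairpin.pair_table
        ms, me = call.mature
        ss, se = call.star
        # exactly the last two mature nts and last two star nts sit outside
        # the paired duplex region
        assert pt[me - 1] == -1 or not (ss <= pt[me - 1] < se)
        assert pt[me - 2] == -1 or not (ss <= pt[me - 2] < se)
        assert pt[me - 3] == ss
        assert pt[ms] == se - 3


class TestDuplexDefects:
    def test_perfect_duplex_has_none(self):
        pt = perfect_pair_table(70, 30, 10)
        mature = (2, 23)
        star = expected_star_interval(mature, pt)
        mism, bulges = duplex_defects(mature, star, pt)
        assert (mism, bulges) == (0, ())

    def test_symmetric_loop_counts_as_mismatches(self):
        pt = perfect_pair_table(70, 30, 10)
        for i in (10, 11):  # open a 2-nt symmetric internal loop
            j = int(pt[i])
            pt[i] = -1
            pt[j] = -1
        mature = (2, 23)
        star = (49, 70)
        mism, bulges = duplex_defects(mature, star, pt)
        assert mism == 2
        assert bulges == ()


class TestRatioGate:
    @pytest.mark.parametrize(
        "ratio,passes", [(0.45, True), (0.39, False), (0.4444, True)]
    )
    def test_threshold(self, ratio, passes):
        assert duplex_read_ratio_gate(ratio) is passes

    def test_ratio_computation(self, hairpin_with_reads, rng):
        seq, hairpin, mature, star = hairpin_with_reads
        background = seq[52:74]  # spans the terminal loop: not callable
        stack = map_reads(
            SmallRnaLibrary("s", {mature: 45, star: 0} | {background: 55}), seq
        )
        (call,) = call_duplexes(stack, hairpin)
        assert duplex_read_ratio(stack, [call]) == pytest.approx(45 / 100)


class TestMirnaLikeFlag:
    @pytest.mark.parametrize(
        "length,products,expected",
        [(1147, 11, True), (1681, 12, True), (120, 1, False), (1500, 2, False)],
    )
    def test_flag(self, length, products, expected):
        assert flag_mirna_like(length, products) is expected
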