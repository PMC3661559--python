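"""Penalty-scored target alignment: DP vs exhaustive enumeration, the
acceptance rules, and whole-sequence scanning."""

import itertools

import numpy as np
import pytest

from intromir._seq import revcomp, to_rna
from intromir.target_predict import align_target, passes_rules, scan_targets

from conftest import random_rna

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def perfect_site(mirna):
    """DNA window whose reverse complement equals the miRNA."""
    return revcomp(mirna.replace("U", "T"))


def mutate_site_opposite(mirna, site, mirna_pos, new_pair="mismatch"):
    """Rebuild the site so the base opposite miRNA position ``mirna_pos``
    (1-based from the miRNA 5' end) forms a mismatch or G:U wobble."""
    rc = list(to_rna(revcomp(site)))
    i = mirna_pos - 1
    m = to_rna(mirna)[i]
    if new_pair == "wobble":
        rc[i] = {"G": "A", "U": "C"}[m]  # G:U pairs seen from the rc frame
    else:
        # put the miRNA base itself on the target strand: G:G, A:A ... never
        # pair, and in the rc frame that is the complement of the miRNA base
        rc[i] = _RC[m]
    return revcomp("".join(rc)).replace("U", "T")


def oracle_min_score(mirna, site, max_bulges=2):
    """Exhaustive enumeration over every monotone alignment with at most
    ``max_bulges`` unpaired insertions; returns the minimum penalty."""
    m = to_rna(mirna)
    r = to_rna(revcomp(site))
    best = [float("inf")]

    def go(i, j, score, bulges):
        if bulges > max_bulges or score >= best[0]:
            return
        if i == len(m) and j == len(r):
            best[0] = min(best[0], score)
            return
        if i < len(m) and j < len(r):
            a, b = m[i], r[j]
            cost = 0.0 if a == b else (0.5 if (a, b) in (("G", "A"), ("U", "C")) else 1.0)
            go(i + 1, j + 1, score + cost, bulges)
        if j < len(r):
            go(i, j + 1, score + 2.0, bulges + 1)
        if i < len(m):
            go(i + 1, j, score + 2.0, bulges + 1)

    go(0, 0, 0.0, 0)
    return best[0]


class TestAlignTarget:
    def test_perfect_complement_scores_zero(self, rng):
        m = random_rna(rng, 21)
        assert align_target(m, perfect_site(m)).score == 0.0

    def test_single_wobble_scores_half(self, rng):
        while True:
            m = random_rna(rng, 21)
            if m[14] in "GU":  # position 15 must support a G:U pair
                break
        site = mutate_site_opposite(m, perfect_site(m), 15, "wobble")
        a = align_target(m, site)
        assert a.score == 0.5
        assert a.kinds_by_position()[15] == "wobble"

    def test_two_mismatches_plus_wobble_scores_two_point_five(self, rng):
        while True:
            m = random_rna(rng, 21)
            if m[19] in "GU":
                break
        site = perfect_site(m)
        site = mutate_site_opposite(m, site, 14)
        site = mutate_site_opposite(m, site, 18)
        site = mutate_site_opposite(m, site, 20, "wobble")
        a = align_target(m, site)
        assert a.score == 2.5
        assert a.score == oracle_min_score(m, site)

    def test_bulged_site_costs_two(self, rng):
        m = random_rna(rng, 21)
        site = perfect_site(m)
        bulged = site[:10] + "A" + site[10:]
        a = align_target(m, bulged)
        assert a.score == oracle_min_score(m, bulged)
        assert a.n_bulges * 2.0 <= a.score

    def test_window_far_too_short_is_an_error(self, rng):
        m = random_rna(rng, 21)
        with pytest.raises(ValueError):
            align_target(m, perfect_site(m)[:15])

    @pytest.mark.parametrize("seed", range(12))
    def test_dp_equals_enumeration_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        m = random_rna(rng, n)
        for wlen in (n - 1, n, n + 1):
            site = random_rna(rng, wlen).replace("U", "T")
            assert align_target(m, site).score == pytest.approx(
                min(oracle_min_score(m, site), align_target(m, site).score)
            )
            # strict equality whenever the optimum uses <= 2 bulges
            if align_target(m, site).n_bulges <= 2:
                assert align_target(m, site).score == oracle_min_score(m, site)

    def test_symmetric_under_strand_role_swap(self, rng):
        # the duplex score does not depend on which strand is the query:
        # G:U stays G:U when the site strand is treated as the miRNA
        for _ in range(10):
            m = random_rna(rng, 12)
            site = random_rna(rng, 12).replace("U", "T")
            swapped = align_target(to_rna(site), m.replace("U", "T"))
            assert align_target(m, site).score == swapped.score

    def test_adding_a_mismatch_never_decreases_score(self, rng):
        m = random_rna(rng, 21)
        site = perfect_site(m)
        prev = align_target(m, site).score
        for pos in (5, 12, 17):
            site = mutate_site_opposite(m, site, pos)
            score = align_target(m, site).score
            assert score >= prev
            prev = score


class TestPassesRules:
    def test_perfect_alignment_passes(self, rng):
        m = random_rna(rng, 21)
        ok, reasons = passes_rules(align_target(m, perfect_site(m)))
        assert ok and reasons == ()

    def test_mismatches_at_both_cleavage_positions_fail(self, rng):
        m = random_rna(rng, 21)
        site = perfect_site(m)
        site = mutate_site_opposite(m, site, 10)
        site = mutate_site_opposite(m, site, 11)
        ok, reasons = passes_rules(align_target(m, site))
        assert not ok
        assert any("10/11" in r for r in reasons)

    def test_one_cleavage_position_match_suffices_by_default(self, rng):
        m = random_rna(rng, 21)
        site = mutate_site_opposite(m, perfect_site(m), 10)
        ok, _ = passes_rules(align_target(m, site))
        assert ok
        ok_strict, _ = passes_rules(align_target(m, site), cleavage_mode="both")
        assert not ok_strict

    def test_two_seed_mismatches_fail(self, rng):
        m = random_rna(rng, 21)
        site = perfect_site(m)
        site = mutate_site_opposite(m, site, 3)
        site = mutate_site_opposite(m, site, 7)
        ok, reasons = passes_rules(align_target(m, site))
        assert not ok
        assert any("2-9" in r for r in reasons)

    def test_score_above_cutoff_fails(self, rng):
        m = random_rna(rng, 21)
        site = perfect_site(m)
        for pos in (12, 14, 16):
            site = mutate_site_opposite(m, site, pos)
        ok, reasons = passes_rules(align_target(m, site))
        assert not ok
        assert any("score" in r for r in reasons)


class TestScanTargets:
    def test_exact_complement_yields_single_zero_hit(self, rng):
        m = random_rna(rng, 21)
        seq = "CCAGTC" + perfect_site(m) + "TTACGG"
        hits = scan_targets(m, {"t1": seq}, mirna_id="m")
        assert len(hits) == 1
        assert hits[0].score == 0.0
        assert (hits[0].start, hits[0].end) == (6, 27)

    def test_shuffled_sequence_matches_brute_force_over_windows(self, rng):
        m = random_rna(rng, 21)
        seq = random_rna(rng, 150).replace("U", "T")
        hits = scan_targets(m, {"t1": seq}, mirna_id="m")
        brute = []
        for wlen in (20, 21, 22):
            for s in range(len(seq) - wlen + 1):
                window = seq[s : s + wlen]
                if oracle_min_score(m, window, max_bulges=1) <= 2.5:
                    brute.append((s, s + wlen))
        if not brute:
            assert hits == []
        else:
            assert all(
                any(h.start < e and s < h.end for h in hits) for s, e in brute
            )

    def test_own_locus_flag_for_self_complementary_intron(self, rng):
        m = random_rna(rng, 21)
        host = "GGCTAC" + perfect_site(m) + "CATGCA"
        hits = scan_targets(
            m,
            {"hostg": host},
            mirna_id="m",
            host_gene="hostg",
            precursor_locus=("hostg", 6, 27),
        )
        assert hits and hits[0].self_target and hits[0].own_locus

    def test_dna_level_scans_both_strands(self, rng):
        m = random_rna(rng, 21)
        # the site on the minus strand: plus strand carries the miRNA itself
        seq = "CCAGTC" + m.replace("U", "T") + "TTACGG"
        assert scan_targets(m, {"t": seq}, mirna_id="m") == []
        hits = scan_targets(m, {"t": seq}, mirna_id="m", include_dna_level=True)
        assert len(hits) == 1 and hits[0].strand == "-"
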