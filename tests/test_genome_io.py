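"""Gene models, intron extraction, collapsed libraries and RPM scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intromir._seq import revcomp
from intromir import genome_io
from intromir.genome_io import (
    GeneModel,
    SmallRnaLibrary,
    extract_introns,
    merge_libraries,
    normalize_rpm,
    read_collapsed_library,
    read_gene_models,
    read_introns_gff3,
    write_gene_models,
    write_introns_gff3,
)

from conftest import random_dna


@pytest.fixture()
def toy_chromosome(rng):
    return {"chr1": random_dna(rng, 300)}


class TestExtractIntrons:
    def test_single_exon_gene_has_no_introns(self, toy_chromosome):
        model = GeneModel("g1", "chr1", "+", ((0, 100),))
        assert extract_introns([model], toy_chromosome) == []

    def test_plus_strand_intron_interval_and_ordinal(self, toy_chromosome):
        # exons (1,100) and (201,300) 1-based inclusive
        model = GeneModel("g1", "chr1", "+", ((0, 100), (200, 300)))
        (intron,) = extract_introns([model], toy_chromosome)
        assert (intron.start, intron.end) == (100, 200)
        assert intron.ordinal == 1
        assert len(intron) == 100
        assert intron.sequence == toy_chromosome["chr1"][100:200]

    def test_minus_strand_sequence_is_reverse_complement(self, toy_chromosome):
        model = GeneModel("g1", "chr1", "-", ((0, 100), (200, 300)))
        (intron,) = extract_introns([model], toy_chromosome)
        assert intron.sequence == revcomp(toy_chromosome["chr1"][100:200])
        assert intron.ordinal == 1

    def test_minus_strand_ordinals_count_from_transcript_5prime(self, toy_chromosome):
        model = GeneModel("g1", "chr1", "-", ((0, 60), (100, 160), (220, 300)))
        introns = extract_introns([model], toy_chromosome)
        by_ordinal = {i.ordinal: (i.start, i.end) for i in introns}
        # transcript 5' end is the genomic right for minus-strand genes
        assert by_ordinal[1] == (160, 220)
        assert by_ordinal[2] == (60, 100)

    def test_exon_outside_chromosome_raises(self, toy_chromosome):
        model = GeneModel("g1", "chr1", "+", ((0, 100), (250, 400)))
        with pytest.raises(IndexError):
            extract_introns([model], toy_chromosome)

    def test_overlapping_exons_rejected_at_model_construction(self):
        with pytest.raises(ValueError):
            GeneModel("g1", "chr1", "+", ((0, 100), (50, 200)))

    def test_exon_plus_intron_concatenation_reconstructs_span(self, toy_chromosome):
        model = GeneModel("g1", "chr1", "+", ((10, 60), (100, 160), (200, 290)))
        introns = sorted(extract_introns([model], toy_chromosome), key=lambda i: i.start)
        parts = []
        for k, (s, e) in enumerate(model.exons):
            parts.append(toy_chromosome["chr1"][s:e])
            if k < len(introns):
                parts.append(introns[k].sequence)
        g0, g1 = model.span
        assert "".join(parts) == toy_chromosome["chr1"][g0:g1]


class TestGff3RoundTrip:
    def test_models_round_trip(self, toy_chromosome, tmp_path):
        models = [
            GeneModel("g1", "chr1", "+", ((0, 100), (200, 300))),
            GeneModel("g2", "chr1", "-", ((10, 50), (90, 140), (180, 240))),
        ]
        path = tmp_path / "models.gff3"
        write_gene_models(models, path)
        back = read_gene_models(path)
        assert [(m.gene_id, m.strand, m.exons) for m in back] == [
            (m.gene_id, m.strand, m.exons) for m in models
        ]

    def test_introns_round_trip_preserves_intervals_and_ordinals(
        self, toy_chromosome, tmp_path
    ):
        model = GeneModel("g1", "chr1", "-", ((0, 60), (100, 160), (220, 300)))
        introns = extract_introns([model], toy_chromosome)
        path = tmp_path / "introns.gff3"
        write_introns_gff3(introns, path)
        back = read_introns_gff3(path, toy_chromosome)
        key = lambda i: (i.start, i.end, i.ordinal, i.sequence)
        assert sorted(map(key, back)) == sorted(map(key, introns))


class TestCollapsedLibrary:
    def test_counts_parsed_and_totalled(self, tmp_path):
        p = tmp_path / "lib.fa"
        p.write_text(">a_x3\nACGTACGTACGTACGTAC\n>b_x7\nTGCATGCATGCATGCATG\n")
        lib = read_collapsed_library(p)
        assert lib.total_reads == 10
        assert lib.n_unique == 2

    def test_duplicate_sequences_merge_by_summation(self, tmp_path):
        p = tmp_path / "lib.fa"
        p.write_text(">a_x2\nACGTACGTACGTACGTAC\n>b_x5\nACGTACGTACGTACGTAC\n")
        lib = read_collapsed_library(p)
        assert lib.entries == {"ACGTACGTACGTACGTAC": 7}

    def test_empty_file_gives_empty_library(self, tmp_path):
        p = tmp_path / "lib.fa"
        p.write_text("")
        lib = read_collapsed_library(p)
        assert lib.total_reads == 0 and lib.n_unique == 0

    def test_alternate_count_dialect(self, tmp_path):
        p = tmp_path / "lib.fa"
        p.write_text(">read1 count=4\nACGTACGTACGTACGTAC\n")
        assert read_collapsed_library(p).total_reads == 4

    def test_malformed_count_names_the_record(self, tmp_path):
        p = tmp_path / "lib.fa"
        p.write_text(">oops\nACGT\n")
        with pytest.raises(ValueError, match="oops"):
            read_collapsed_library(p)

    def test_merge_libraries_pools_counts(self):
        a = SmallRnaLibrary("a", {"ACGT": 2, "GGGG": 1})
        b = SmallRnaLibrary("b", {"ACGT": 3})
        merged = merge_libraries([a, b])
        assert merged.entries == {"ACGT": 5, "GGGG": 1}


class TestNormalizeRpm:
    @pytest.mark.parametrize(
        "count,total,factor,expected",
        [(0, 1000, 2, 0.0), (500, 10**6, 2, 1000.0), (250, 5 * 10**5, 1, 500.0)],
    )
    def test_closed_form(self, count, total, factor, expected):
        assert normalize_rpm(count, total, factor) == pytest.approx(expected)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_rpm(5, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        count=st.integers(0, 10**6),
        total=st.integers(1, 10**7),
        scale=st.integers(1, 100),
    )
    def test_linear_in_count_and_scale_invariant(self, count, total, scale):
        base = normalize_rpm(count, total)
        assert normalize_rpm(scale * count, total) == pytest.approx(scale * base)
        assert normalize_rpm(scale * count, scale * total) == pytest.approx(base)
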