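"""Feature catalogs, peak classification priority, TSS signal matrices."""

import numpy as np
import pytest

from retnuc import (
    FEATURE_CLASSES,
    GenomeTable,
    GenomicInterval,
    RegionSet,
    build_feature_catalog,
    classify_peak,
    classify_peaks,
    summarize_classes,
    tss_signal_matrix,
)
from retnuc.annotation import build_gene, read_genes_tsv, write_genes_tsv


@pytest.fixture
def big_genome():
    return GenomeTable([("chr1", 100_000), ("chr2", 100_000)])


@pytest.fixture
def plus_gene():
    # span [10000,20000), exons [10000,12000) and [18000,20000), CDS 11000-19000
    return build_gene(
        "gplus", "chr1", "+", 10_000, 20_000, 11_000, 19_000,
        [(10_000, 12_000), (18_000, 20_000)],
    )


@pytest.fixture
def minus_gene():
    return build_gene(
        "gminus", "chr2", "-", 10_000, 20_000, 11_000, 19_000,
        [(10_000, 12_000), (18_000, 20_000)],
    )


class TestCatalogGeometry:
    def test_plus_strand_tss_and_promoter(self, big_genome, plus_gene):
        cat = build_feature_catalog([plus_gene], big_genome, promoter_len=2000)
        tss = cat.class_regions["TSS"].intervals[0]
        prom = cat.class_regions["PROMOTER"].intervals[0]
        assert (tss.start, tss.end) == (10_000, 10_001)
        assert (prom.start, prom.end) == (8_000, 10_000)

    def test_minus_strand_tss_and_promoter(self, big_genome, minus_gene):
        cat = build_feature_catalog([minus_gene], big_genome, promoter_len=2000)
        tss = cat.class_regions["TSS"].intervals[0]
        prom = cat.class_regions["PROMOTER"].intervals[0]
        assert (tss.start, tss.end) == (19_999, 20_000)
        assert (prom.start, prom.end) == (20_000, 22_000)

    def test_promoter_clipped_at_chromosome_start(self, big_genome):
        g = build_gene("g0", "chr1", "+", 500, 3_000, 600, 2_900, [(500, 3_000)])
        cat = build_feature_catalog([g], big_genome, promoter_len=2000)
        prom = cat.class_regions["PROMOTER"].intervals[0]
        assert (prom.start, prom.end) == (0, 500)

    def test_introns_are_span_minus_exons(self, plus_gene):
        introns = plus_gene.introns
        assert [(iv.start, iv.end) for iv in introns] == [(12_000, 18_000)]

    def test_gene_outside_genome_rejected(self, plus_gene):
        small = GenomeTable([("chr1", 15_000)])
        with pytest.raises(Exception, match="exceeds"):
            build_feature_catalog([plus_gene], small)


class TestClassification:
    def test_tss_beats_promoter(self, big_genome, plus_gene):
        cat = build_feature_catalog([plus_gene], big_genome)
        peak = GenomicInterval("chr1", 9_500, 10_100)  # spans promoter + TSS
        assert classify_peak(peak, cat) == "TSS"

    def test_cds_beats_intron(self, big_genome, plus_gene):
        cat = build_feature_catalog([plus_gene], big_genome)
        peak = GenomicInterval("chr1", 11_500, 12_500)  # CDS into intron
        assert classify_peak(peak, cat) == "CDS"

    def test_intergenic_fallthrough(self, big_genome, plus_gene):
        cat = build_feature_catalog([plus_gene], big_genome)
        assert classify_peak(GenomicInterval("chr1", 50_000, 50_200), cat) == "INTERGENIC"

    def test_every_peak_gets_exactly_one_class(self, big_genome, plus_gene, minus_gene):
        cat = build_feature_catalog([plus_gene, minus_gene], big_genome)
        rng = np.random.default_rng(4)
        ivs = [
            GenomicInterval(
                ["chr1", "chr2"][int(rng.integers(0, 2))],
                int(s := rng.integers(0, 99_000)),
                int(s) + int(rng.integers(1, 600)),
            )
            for _ in range(300)
        ]
        peaks = RegionSet(ivs, big_genome)
        labels = classify_peaks(peaks, cat)
        assert len(labels) == len(peaks)
        assert set(labels) <= set(FEATURE_CLASSES)
        props = summarize_classes(peaks, cat)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_classification_invariant_to_gene_order(self, big_genome, plus_gene, minus_gene):
        rng = np.random.default_rng(5)
        ivs = [
            GenomicInterval("chr1", int(s := rng.integers(0, 99_000)), int(s) + 300)
            for _ in range(100)
        ]
        peaks = RegionSet(ivs, big_genome)
        cat_a = build_feature_catalog([plus_gene, minus_gene], big_genome)
        cat_b = build_feature_catalog([minus_gene, plus_gene], big_genome)
        assert list(classify_peaks(peaks, cat_a)) == list(classify_peaks(peaks, cat_b))

    def test_strand_flip_mirror_leaves_summary_unchanged(self, big_genome):
        L = 100_000
        g = build_gene(
            "g", "chr1", "+", 10_000, 20_000, 11_000, 19_000,
            [(10_000, 12_000), (18_000, 20_000)],
        )
        # mirrored copy: coordinates reflected, strand flipped
        gm = build_gene(
            "gm", "chr1", "-", L - 20_000, L - 10_000, L - 19_000, L - 11_000,
            [(L - 20_000, L - 18_000), (L - 12_000, L - 10_000)],
        )
        rng = np.random.default_rng(6)
        ivs = [
            GenomicInterval("chr1", int(s := rng.integers(0, L - 600)), int(s) + 400)
            for _ in range(200)
        ]
        mirrored = [
            GenomicInterval("chr1", L - iv.end, L - iv.start) for iv in ivs
        ]
        cat_f = build_feature_catalog([g], big_genome)
        cat_m = build_feature_catalog([gm], big_genome)
        p1 = summarize_classes(RegionSet(ivs, big_genome), cat_f)
        p2 = summarize_classes(RegionSet(mirrored, big_genome), cat_m)
        assert p1 == p2

    def test_summary_proportions_count(self, big_genome, plus_gene):
        cat = build_feature_catalog([plus_gene], big_genome)
        ivs = [GenomicInterval("chr1", 13_000 + i, 13_001 + i) for i in range(7)]
        ivs += [GenomicInterval("chr1", 60_000 + i, 60_001 + i) for i in range(3)]
        props = summarize_classes(RegionSet(ivs, big_genome), cat)
        assert props["INTRON"] == pytest.approx(0.7)
        assert props["INTERGENIC"] == pytest.approx(0.3)

    def test_empty_peaks_error(self, big_genome, plus_gene):
        cat = build_feature_catalog([plus_gene], big_genome)
        with pytest.raises(ValueError, match="empty"):
            summarize_classes(RegionSet([], big_genome), cat)


class TestTssMatrix:
    def test_column_count(self, big_genome, plus_gene):
        cat = build_feature_catalog([plus_gene], big_genome)
        frags = RegionSet([GenomicInterval("chr1", 9_990, 10_100)], big_genome)
        m, ids = tss_signal_matrix(frags, cat, flank=500, bin_size=10)
        assert m.shape == (1, 100)
        assert ids == ["gplus"]

    def test_strand_symmetry(self, big_genome, plus_gene, minus_gene):
        cat = build_feature_catalog([plus_gene, minus_gene], big_genome)
        # one fragment 30 bp downstream of each TSS in gene orientation
        frags = RegionSet(
            [
                GenomicInterval("chr1", 10_030, 10_130),  # + strand TSS at 10000
                GenomicInterval("chr2", 19_870, 19_970),  # - strand TSS at 19999
            ],
            big_genome,
        )
        m, ids = tss_signal_matrix(frags, cat, flank=500, bin_size=10)
        assert m.shape == (2, 100)
        assert np.array_equal(m[0], m[1])

    def test_skip_zeros_drops_empty_rows(self, big_genome, plus_gene, minus_gene):
        cat = build_feature_catalog([plus_gene, minus_gene], big_genome)
        frags = RegionSet([GenomicInterval("chr1", 10_000, 10_100)], big_genome)
        m, ids = tss_signal_matrix(frags, cat, flank=500, bin_size=10, skip_zeros=True)
        assert ids == ["gplus"]

    def test_flank_not_divisible_rejected(self, big_genome, plus_gene):
        cat = build_feature_catalog([plus_gene], big_genome)
        frags = RegionSet([], big_genome)
        with pytest.raises(ValueError, match="divisible"):
            tss_signal_matrix(frags, cat, flank=500, bin_size=7)


class TestGeneIO:
    def test_round_trip(self, tmp_path, big_genome, plus_gene, minus_gene):
        path = tmp_path / "genes.tsv"
        write_genes_tsv([plus_gene, minus_gene], str(path))
        back = read_genes_tsv(str(path), big_genome)
        assert [g.gene_id for g in back] == ["gplus", "gminus"]
        for a, b in zip([plus_gene, minus_gene], back):
            assert (a.span.start, a.span.end, a.strand) == (
                b.span.start,
                b.span.end,
                b.strand,
            )
            assert [(x.start, x.end) for x in a.cds_blocks] == [
                (x.start, x.end) for x in b.cds_blocks
            ]
            assert [(x.start, x.end) for x in a.utr5_blocks] == [
                (x.start, x.end) for x in b.utr5_blocks
            ]

    def test_utr_sides_follow_strand(self, plus_gene, minus_gene):
        # same block layout: 5' UTR is left of CDS on +, right of CDS on -
        assert [(b.start, b.end) for b in plus_gene.utr5_blocks] == [(10_000, 11_000)]
        assert [(b.start, b.end) for b in minus_gene.utr5_blocks] == [(19_000, 20_000)]
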