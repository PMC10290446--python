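"""Generator validity, determinism, and planted-structure recovery (light)."""

import numpy as np
import pytest

from retnuc import ShuffleConfig, SimulationConfig, bin_abundance, permutation_test
from retnuc.annotation import build_feature_catalog
from retnuc.fragments import partition_fragments
from retnuc.regions import RegionSet
from retnuc.rna import annotate_abundance, build_table3, fisher_class_vs_absent
from retnuc.simulate import (
    lognormal_width_sampler,
    make_abundance,
    make_fragments,
    make_genes,
    make_genome,
    make_repeat_set,
    plant_peaks,
)


@pytest.fixture(scope="module")
def scenario():
    cfg = SimulationConfig(seed=17)
    genome = make_genome(cfg)
    rng = np.random.default_rng(17)
    genes = make_genes(cfg, genome, rng)
    catalog = build_feature_catalog(genes, genome, promoter_len=cfg.promoter_len)
    return cfg, genome, genes, catalog


class TestGenome:
    def test_lengths_and_total(self):
        cfg = SimulationConfig(chrom_lengths=(1_000_000, 1_000_000))
        g = make_genome(cfg)
        assert g.total_length == 2_000_000

    def test_seed_determinism(self):
        a = make_genome(SimulationConfig(seed=3))
        b = make_genome(SimulationConfig(seed=3))
        assert a.names == b.names and a.total_length == b.total_length

    def test_zero_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(chrom_lengths=())


class TestGenes:
    def test_count_and_validity(self, scenario):
        cfg, genome, genes, _ = scenario
        assert len(genes) == cfg.n_genes
        for g in genes:
            genome.validate(g.span)
            exonic = sum(b.width for b in g.exon_blocks)
            intronic = sum(b.width for b in g.introns)
            assert exonic + intronic == g.span.width

    def test_non_overlapping_spans(self, scenario):
        _, _, genes, _ = scenario
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.span)
        for spans in by_chrom.values():
            spans = sorted(spans, key=lambda iv: iv.start)
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start

    def test_both_strands_roughly_balanced(self, scenario):
        _, _, genes, _ = scenario
        plus = sum(1 for g in genes if g.strand == "+")
        # binomial(500, 0.5): +/- 4 sd band
        assert 250 - 45 <= plus <= 250 + 45

    def test_genome_too_small_rejected(self):
        cfg = SimulationConfig(chrom_lengths=(100_000,), n_genes=500)
        with pytest.raises(ValueError, match="too small"):
            make_genes(cfg, make_genome(cfg), np.random.default_rng(0))


class TestPlantPeaks:
    def test_uniform_placement_under_unit_rho(self, scenario):
        cfg, genome, _, catalog = scenario
        prom = catalog.class_regions["PROMOTER"]
        sampler = lognormal_width_sampler(270, 0.35)
        peaks = plant_peaks(
            1500, sampler, genome, [("PROMOTER", prom)], {}, np.random.default_rng(1)
        )
        res = permutation_test(
            peaks, prom, genome, ShuffleConfig(n_perms=100, seed=2)
        )
        assert res.label == "none"

    def test_planted_enrichment_recovered(self, scenario):
        cfg, genome, _, catalog = scenario
        prom = catalog.class_regions["PROMOTER"]
        sampler = lognormal_width_sampler(270, 0.35)
        peaks = plant_peaks(
            2000, sampler, genome, [("PROMOTER", prom)], {"PROMOTER": 3.0},
            np.random.default_rng(3),
        )
        res = permutation_test(
            peaks, prom, genome, ShuffleConfig(n_perms=200, seed=4)
        )
        assert res.label == "enriched"
        assert 2.4 <= res.fc <= 3.6

    def test_planted_depletion_recovered(self, scenario):
        cfg, genome, genes, catalog = scenario
        rng = np.random.default_rng(5)
        excl = RegionSet(
            [g.span for g in genes] + catalog.class_regions["PROMOTER"].intervals,
            genome,
        )
        line = make_repeat_set(genome, 3000, 800, rng, exclude=excl, label="LINE")
        sampler = lognormal_width_sampler(270, 0.35)
        peaks = plant_peaks(
            2000, sampler, genome, [("LINE", line)], {"LINE": 0.3}, rng
        )
        res = permutation_test(
            peaks, line, genome, ShuffleConfig(n_perms=200, seed=6)
        )
        assert res.label == "depleted"

    def test_infeasible_rho_rejected(self, scenario):
        cfg, genome, genes, catalog = scenario
        rng = np.random.default_rng(7)
        line = make_repeat_set(genome, 4000, 800, rng, label="LINE")
        sampler = lognormal_width_sampler(270, 0.35)
        with pytest.raises(ValueError, match="infeasible"):
            plant_peaks(100, sampler, genome, [("LINE", line)], {"LINE": 5.0}, rng)

    def test_width_distribution_matches_config(self, scenario):
        cfg, genome, _, catalog = scenario
        sampler = lognormal_width_sampler(270, 0.35)
        peaks = plant_peaks(
            2000, sampler, genome, [], {}, np.random.default_rng(8)
        )
        assert abs(peaks.widths().mean() - 270) < 15


class TestAbundance:
    def test_all_four_classes_populated_at_defaults(self, scenario):
        cfg, genome, genes, _ = scenario
        peaks = plant_peaks(
            cfg.n_peaks_sn,
            lognormal_width_sampler(141, 0.25),
            genome,
            [],
            {},
            np.random.default_rng(9),
        )
        df = make_abundance(cfg, genes, genome, peaks, np.random.default_rng(10))
        classes = df["fpkm"].map(bin_abundance)
        assert set(classes) == {"absent", "low", "intermediate", "high"}

    def test_coupling_strengthens_fisher_signal(self, scenario):
        cfg, genome, genes, _ = scenario
        peaks = plant_peaks(
            300,
            lognormal_width_sampler(141, 0.25),
            genome,
            [],
            {},
            np.random.default_rng(11),
        )
        ps = []
        for beta in (0.0, 4.0):
            c = SimulationConfig(seed=12, beta=beta)
            df = make_abundance(c, genes, genome, peaks, np.random.default_rng(12))
            ann = annotate_abundance(df, genes, genome, {"SN": peaks})
            tab = build_table3(ann.assign(
                abundance_class=ann["fpkm"].map(bin_abundance)
            ), "low", "near_SN")
            ps.append(fisher_class_vs_absent(tab))
        assert ps[1] < ps[0]


class TestFragments:
    def test_component_recovery_above_95_percent(self, scenario):
        cfg, genome, _, catalog = scenario
        rng = np.random.default_rng(13)
        mn = plant_peaks(500, lognormal_width_sampler(270, 0.35), genome, [], {}, rng)
        sn = plant_peaks(100, lognormal_width_sampler(141, 0.25), genome, [], {}, rng)
        records, labels = make_fragments(cfg, mn, sn, genome, rng)
        lengths = np.array([r.template_length for r in records])
        predicted = np.where(lengths <= 110, "sn", np.where(lengths <= 1000, "mn", "?"))
        assert (predicted == labels).mean() >= 0.95
        part = partition_fragments(records, genome)
        assert len(part.sn) + len(part.mn) + part.discarded == len(records)

    def test_zero_fragments(self, scenario):
        cfg, genome, _, _ = scenario
        c = SimulationConfig(seed=1, n_fragments=0)
        records, labels = make_fragments(
            c, RegionSet([], genome), RegionSet([], genome), genome
        )
        assert records == [] and len(labels) == 0

    def test_seeded_determinism(self, scenario):
        cfg, genome, _, _ = scenario
        rng = np.random.default_rng(14)
        mn = plant_peaks(50, lognormal_width_sampler(270, 0.35), genome, [], {}, rng)
        sn = plant_peaks(20, lognormal_width_sampler(141, 0.25), genome, [], {}, rng)
        small = SimulationConfig(seed=1, n_fragments=500)
        a, la = make_fragments(small, mn, sn, genome, np.random.default_rng(15))
        b, lb = make_fragments(small, mn, sn, genome, np.random.default_rng(15))
        assert a == b and (la == lb).all()
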