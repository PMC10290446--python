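# retnuc

Co-location analysis of retained-nucleosome MNase-seq peaks with genomic
features, built for sperm chromatin studies.

In mature mammalian sperm most histones are replaced by protamines, but a
small fraction of nucleosomes is retained at specific genomic positions.
MNase digestion of sperm chromatin followed by paired-end sequencing yields
a mono-nucleosomal (MN, ~147 bp) and a sub-nucleosomal (SN, <~110 bp)
fragment population; where their peaks fall — promoters, UTRs, coding
sequence, RNA loci, trait-associated regions, repeat elements — speaks to
whether nucleosome retention is programmatic or random. `retnuc` implements
the statistical core of that analysis as a tested, reusable library and CLI:

* **Fragment partitioning** — split paired-end fragments into SN
  (template length ≤ 110 bp) and MN (111–1000 bp) fractions; binned
  genome-wide coverage and replicate Pearson correlation (with
  skip-zeros / robust outlier filtering).
* **Feature annotation** — strand-aware per-gene catalogs (TSS, promoter,
  5'/3' UTR, CDS, intron, intergenic), single-class peak classification by
  a configurable priority order, and TSS-centered signal matrices.
* **Permutation enrichment** — the width-preserving shuffle null. For a
  query peak set *Q* and feature set *S*, the observed overlap count
  `obs = #{q ∈ Q : q shares ≥1 bp with S}` is compared with counts from
  *N* random re-placements of *Q* (same width multiset, chromosomes drawn
  ∝ length). The empirical two-sided p is
  `p = #{i : |cᵢ − c̄| ≥ |obs − c̄|} / N`, the fold change is
  `FC = obs / c̄`, and a comparison is *enriched* when p < 0.001 and
  FC ≥ 1.5, *depleted* when p < 0.001 and FC ≤ 0.66.
* **RNA co-location** — FPKM abundance classes (absent <1, low 1–10,
  intermediate 10–100, high ≥100), a strict <5 kb gene-to-peak proximity
  rule, two-tailed Fisher exact tests of each expressed class against the
  absent class, and Kruskal–Wallis comparison of log2(FPKM+1) profiles.
* **Ortholog overlap** — genes within <500 bp of (motif-bearing) peaks,
  ortholog mapping, and an upper-tail hypergeometric test
  P(X ≥ k | N, K, n) for overlap with a reference gene list.
* **Synthetic data** — genomes, gene annotations, abundance tables,
  fragment mixtures and peak sets with *plantable* enrichment: a rejection
  sampler places peaks so that a planted factor ρ per feature class is
  exactly what the permutation FC estimates.

## Worked example

Generate a synthetic scenario and test a planted promoter enrichment:

```python
import numpy as np
from retnuc import ShuffleConfig, SimulationConfig, permutation_test
from retnuc.annotation import build_feature_catalog
from retnuc.simulate import (
    lognormal_width_sampler, make_genes, make_genome, plant_peaks,
)

cfg = SimulationConfig(seed=3)              # 10-Mbp genome, 500 genes
genome = make_genome(cfg)
rng = np.random.default_rng(3)
genes = make_genes(cfg, genome, rng)
catalog = build_feature_catalog(genes, genome)

prom = catalog.class_regions["PROMOTER"]
peaks = plant_peaks(                        # 2,000 MN-like peaks, rho = 3
    2000, lognormal_width_sampler(270, 0.35), genome,
    [("PROMOTER", prom)], {"PROMOTER": 3.0}, rng,
)
res = permutation_test(peaks, prom, genome, ShuffleConfig(n_perms=200, seed=11))
print(res.observed, round(res.perm_mean, 2), res.p_formatted,
      round(res.fc, 2), res.label)
```

prints

```
689 221.03 <0.005 3.12 enriched
```

i.e. 689 of the 2,000 peaks overlap a promoter against a permutation mean
of 221.03, no permutation deviated as far from its mean as the observed
count (p below the 1/200 resolution), and the recovered fold change 3.12
matches the planted factor ρ = 3 within sampling error — so the peak set
is labelled enriched at promoters.

The same analysis runs from the shell:

```
retnuc simulate --seed 3 --outdir sim/
retnuc enrich --query sim/peaks_mn.bed --subject sn=sim/peaks_sn.bed \
    --genome sim/chrom.sizes --n-perms 1000 --seed 17 --out enr.tsv
retnuc all --config run.yaml        # full report bundle
```

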