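# Methods

## The model

Retained nucleosomes in sperm are observed as peaks called from MNase-seq
fragment coverage. The scientific question is positional: do peaks co-locate
with a feature set (promoters, UTRs, RNA loci, GWAS regions, repeats,
cross-species peak maps) more or less often than expected by chance, given
only the number of peaks and their width distribution?

The chance model is a width-preserving randomization. Each of the `N`
permutations re-places every query interval uniformly at random, wholly
inside a chromosome, with the chromosome drawn with probability
proportional to its length; the multiset of interval widths is preserved
exactly and shuffled intervals may overlap each other (no exclusion
regions by default, matching the default behaviour of the standard
shuffle tools; an exclusion set and a same-chromosome placement mode are
available as options). The test statistic is the number of *query
intervals* that share at least 1 bp with the subject set — per-query
counting, not per-pair, so the count is bounded by the peak count and is
insensitive to how fragmented the subject annotation is (per-pair
counting is available via `counting_mode="pairs"`).

The empirical two-sided p-value is the proportion of permutations whose
count deviates from the permutation mean at least as much as the observed
count; deviations exactly equal to the observed deviation are counted
(the conservative choice). With the observed count excluded from the
permutation set, p = 0 is possible and is reported as `<1/N` (e.g.
`<0.001` at N = 1000). An optional `(b+1)/(N+1)` estimator exists but is
off by default to match the reporting convention of the field. Fold
change is observed / permutation mean; a comparison is *enriched* when
p < 0.001 and FC ≥ 1.5 and *depleted* when p < 0.001 and FC ≤ 0.66.
The SE column of the report is the standard deviation of the permutation
counts — that definition is consistent with the magnitudes printed in the
sperm chromatin literature this package targets — and is trivially
switchable to SD/√N.

Reproducibility: one root seed; permutation *i* draws from spawned
substream *i* (`numpy.random.SeedSequence`), so results are independent
of execution order and parallelization.

## Fragment partitioning

Fractions are separated purely on mapped template length (leftmost mate
start to rightmost mate end): SN ≤ 110 bp, 111 ≤ MN ≤ 1000 bp, the rest
discarded. The bounds are parameters; the defaults are the values used in
the sperm MNase-seq protocols this package reimplements. Whether
soft-clipped bases should count toward the insert is an upstream aligner
question; mapped-span semantics are used here. Replicate pooling is plain
record-list concatenation.

Replicate agreement uses Pearson correlation of binned genome-wide
coverage (a fragment increments every bin it overlaps). Two filters
mirror common coverage-QC practice: `skip_zeros` drops bins where both
replicates are zero, and `remove_outliers` drops bins where either value
exceeds median + k·MAD of its vector. The plotting tool the field uses
for this step does not document its outlier rule, so the robust
median/MAD filter with k = 200 (matching that tool's extreme-outlier
intent on count data whose MAD is typically 1) was adopted as this
package's own documented rule; both filters are off by default.

## Peak classification

Gene features are derived per gene: a 1-bp TSS site (`span.start` on +,
`span.end − 1` on −; optionally expanded ±w), a promoter window of
`promoter_len` bp immediately upstream of the TSS (default 2,000 bp — a
common convention; the exact window used by prior pipelines is not
standardized, so it is a parameter and absolute per-class counts depend
on it), UTR and CDS blocks from the exon/CDS structure, and introns as
span minus exons. A peak gets exactly one class: the highest-priority
class it overlaps by ≥1 bp against the union catalog over all genes, with
default priority TSS > PROMOTER > UTR5 > UTR3 > CDS > INTRON >
INTERGENIC. Rare, specific features come first so promoters cannot
absorb TSS hits; the order is configurable.

TSS-centered matrices cover [tss − flank, tss + flank) in fixed-width
bins (default 500/10). On the minus strand the window is the exact mirror
of the plus-strand window around the TSS base, `[tss − flank + 1,
tss + flank + 1)`, and the row is reversed so columns always run 5'→3';
this makes a fragment at +d downstream of a plus-strand TSS and its
mirror at a minus-strand TSS produce identical rows.

## RNA co-location and gene-set overlap

Genes are binned by FPKM into absent [0,1), low [1,10), intermediate
[10,100) and high [100,∞). A gene co-locates with a peak set when its
span (whole-gene coordinates, not the TSS) lies strictly less than
5,000 bp from the nearest peak; overlap means distance 0. Each expressed
class is tested against the absent class with the two-tailed Fisher exact
test under the probability-mass convention (sum of hypergeometric point
masses not exceeding the observed table's), computed in log space via
scipy — safe for counts of order 10⁴. Abundance profiles are compared
with Kruskal–Wallis on log2(FPKM + 1); the pseudo-count only affects the
box-plot summaries, never the rank-based test.

The cross-species overlap test selects genes strictly within 500 bp of a
peak, maps them through a possibly many-to-many ortholog table (unmapped
genes dropped and counted), and evaluates the upper-tail hypergeometric
probability P(X ≥ k) of the overlap with a reference list. The universe
size N is a required argument — published analyses of this kind rarely
state their universe, and the p-value is meaningless without it, so it is
never defaulted.

## Synthetic data

The generator emulates the statistical shape of the study conditions, at
a desk scale chosen to keep the full suite fast: a 10-Mbp genome over
four chromosomes, 500 non-overlapping genes (spans 2–12 kb, 2–8 exons,
both strands), 2,000 MN-like and 300 SN-like peaks, 20,000 fragments.
Peak widths are lognormal with arithmetic means 270 bp (MN, σ = 0.35)
and 141 bp (SN, σ = 0.25), matching the reported mean widths. Fragment
template lengths are a two-component normal mixture, 147 ± 10 bp (weight
0.9) and 95 ± 10 bp (weight 0.1); the weight reflects the roughly 9:1
MN:SN read ratio of the pooled sperm libraries and the separation makes
the expected misclassification across the 110/111 boundary ≈ 0.6%
(normal tails), so the partition recovers the generating component for
≥95% of fragments. FPKM is log-normal, log2 FPKM ~ N(0, 3), which
populates all four abundance classes at realistic proportions (roughly
half absent, few percent high); genes within 5 kb of a peak receive a
+β log2 shift (default β = 1; β = 0 is the calibration null).

Planted enrichment uses rejection sampling so the planted factor ρ is
exactly what the permutation FC estimates. Naive acceptance ∝ ρ(class)
would deliver FC = ρ/Z with Z = Σ_c ρ(c)·p(c), where p(c) is the
uniform-placement rate of class c. Instead, the classes without a
specified ρ (including the background) share a common weight α solving
Σ_c w(c)·p(c) = 1, with p(c) estimated by Monte Carlo uniform placement
(max(4000, 2·n) candidates; the induced FC error is well under 1%). A ρ
map demanding more than the whole placement mass (α ≤ 0) raises an
error. Candidate class assignment uses the same first-overlap priority as
classification, so planting on overlapping feature sets (e.g. TSS inside
promoters) is well defined; the repeat-set builder can keep repeats at a
margin from genes and promoters so repeat-targeted planting stays
decoupled from gene-feature planting.

What the generator does **not** emulate: sequence content (no GC or
mappability structure, no FASTQ), fragmentation or duplicate artifacts,
peak-calling uncertainty (peaks are planted, not called from coverage),
linkage between neighbouring features, and chromosome-scale
heterogeneity. Passing tests therefore validate the statistical
machinery — counting, the null, the estimators, the thresholds — not the
biology of any particular dataset.

## Numerical and design choices

* Coordinates are 0-based half-open (BED) throughout; 1-based inputs must
  be converted at the boundary. Chromosome names match exactly (no
  `chr`-prefix normalization).
* Distances are edge gaps; overlapping or abutting intervals are at
  distance 0; ties between subject intervals resolve to the minimum with
  no left/right preference; "below 5 kb" and "less than 500 bp" are
  strict inequalities.
* Overlap counting and shuffling are vectorized numpy `searchsorted`
  routines over a linearized genome (subject intervals merged once per
  test); they are cross-checked against O(n·m) brute force in the test
  suite. Merging across a chromosome boundary is harmless because the
  linearization is order-preserving and every query lies within one
  chromosome.
* Fisher, hypergeometric, Kruskal–Wallis and Pearson statistics go
  through scipy; the test suite holds them against independent
  enumeration oracles written in exact integer arithmetic. The oracle
  comparison is exhaustive for all 2×2 tables with total ≤ 30 and all
  hypergeometric configurations with N ≤ 20, and samples seeded random
  cases up to total/N = 60, keeping the check well inside a couple of
  minutes while still covering the full small-table lattice.
* An all-tied Kruskal–Wallis input returns H = 0, p = 1 by convention.
  A zero permutation mean leaves FC undefined (reported missing with a
  warning) rather than infinite.
* Report formatting mirrors the field's summary tables (means/SE/FC to
  2 d.p., p as `<0.001` below resolution) with raw full-precision columns
  alongside; outputs are byte-identical across same-seed reruns.

## Known limitations

* The empirical p has resolution 1/N; at N = 1000 nothing below `<0.001`
  can be claimed.
* Integer overlap counts make the null p slightly super-uniform for
  small counts (ties all count toward p). The calibration check therefore
  uses configurations with expected counts in the hundreds; very sparse
  subjects will show conservative p-values.
* The shuffle null is not GC- or gap-aware and does not model circular
  shifts; those nulls are out of scope.
* Gene models are single-isoform (one record per gene id); transcript
  isoform resolution and full GFF3/GTF parsing are out of scope.
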