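"""Gene-feature catalogs, peak classification and TSS-centered signal matrices.

Each peak is assigned to exactly one gene-feature class by a configurable
priority order (default TSS > PROMOTER > UTR5 > UTR3 > CDS > INTRON >
INTERGENIC): the peak gets the highest-priority class whose intervals it
overlaps by at least 1 bp, against the union catalog over all genes. Rare,
specific features come first so that promoters do not absorb TSS hits.

The promoter is a strand-aware window of ``promoter_len`` bp immediately
upstream of the TSS (default 2,000 bp), clipped to chromosome bounds and
excluding the TSS base itself. The TSS feature is a single base by default,
optionally expanded by ``tss_halfwidth``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .regions import (
    GenomeTable,
    GenomicInterval,
    GeneModel,
    RegionError,
    RegionSet,
    _overlap_flags_linear,
)

__all__ = [
    "FEATURE_CLASSES",
    "FeatureCatalog",
    "build_feature_catalog",
    "classify_peak",
    "classify_peaks",
    "summarize_classes",
    "tss_signal_matrix",
    "read_genes_tsv",
    "write_genes_tsv",
]

#: Exhaustive, mutually exclusive peak classes, in default priority order.
FEATURE_CLASSES = ("TSS", "PROMOTER", "UTR5", "UTR3", "CDS", "INTRON", "INTERGENIC")


class FeatureCatalog:
    """Per-class union interval sets derived from a gene annotation.

    ``class_regions`` maps every class except INTERGENIC to a RegionSet;
    INTERGENIC is the complement of gene spans and promoters and is the
    fall-through class in classification.
    """

    def __init__(
        self,
        class_regions: dict[str, RegionSet],
        genome: GenomeTable,
        genes: Sequence[GeneModel],
        priority: Sequence[str] = FEATURE_CLASSES,
    ):
        self.class_regions = class_regions
        self.genome = genome
        self.genes = list(genes)
        self.priority = tuple(priority)
        if self.priority[-1] != "INTERGENIC":
            raise ValueError("priority order must end with INTERGENIC")

    def intergenic(self) -> RegionSet:
        """Complement of gene spans and promoters over the genome."""
        occupied_ivs: list[GenomicInterval] = []
        for g in self.genes:
            occupied_ivs.append(g.span)
        occupied_ivs.extend(self.class_regions["PROMOTER"].intervals)
        occupied = RegionSet(occupied_ivs, self.genome)
        off = self.genome.offsets()
        bounds = [(off[n], off[n] + self.genome[n], n) for n in self.genome.names]
        ms, me = occupied.merged_linear()
        out: list[GenomicInterval] = []
        j = 0
        for lo, hi, name in bounds:
            pos = lo
            while j < len(ms) and ms[j] < hi:
                s, e = max(int(ms[j]), lo), min(int(me[j]), hi)
                if s > pos:
                    out.append(GenomicInterval(name, pos - lo, s - lo))
                pos = max(pos, e)
                if me[j] > hi:
                    break  # merged run continues into the next chromosome
                j += 1
            if pos < hi:
                out.append(GenomicInterval(name, pos - lo, hi - lo))
        return RegionSet(out, self.genome, label="INTERGENIC")


def build_feature_catalog(
    genes: Sequence[GeneModel],
    genome: GenomeTable,
    promoter_len: int = 2000,
    tss_halfwidth: int = 0,
    priority: Sequence[str] = FEATURE_CLASSES,
) -> FeatureCatalog:
    """Build union feature intervals (TSS, promoter, UTRs, CDS, introns)."""
    if promoter_len < 1:
        raise ValueError("promoter_len must be >= 1")
    buckets: dict[str, list[GenomicInterval]] = {
        c: [] for c in FEATURE_CLASSES if c != "INTERGENIC"
    }
    for g in genes:
        genome.validate(g.span)
        chrom_len = genome[g.chrom]
        tss = g.tss
        ts = max(0, tss - tss_halfwidth)
        te = min(chrom_len, tss + 1 + tss_halfwidth)
        buckets["TSS"].append(GenomicInterval(g.chrom, ts, te))
        if g.strand == "+":
            ps, pe = max(0, tss - promoter_len), tss
        else:
            ps, pe = tss + 1, min(chrom_len, tss + 1 + promoter_len)
        if ps < pe:
            buckets["PROMOTER"].append(GenomicInterval(g.chrom, ps, pe))
        buckets["UTR5"].extend(g.utr5_blocks)
        buckets["UTR3"].extend(g.utr3_blocks)
        buckets["CDS"].extend(g.cds_blocks)
        buckets["INTRON"].extend(g.introns)
    class_regions = {
        c: RegionSet(ivs, genome, label=c) for c, ivs in buckets.items()
    }
    return FeatureCatalog(class_regions, genome, genes, priority=priority)


def classify_peaks(peaks: RegionSet, catalog: FeatureCatalog) -> np.ndarray:
    """Class label per peak (array of str), by the catalog's priority order."""
    labels = np.full(len(peaks), "INTERGENIC", dtype=object)
    unassigned = np.ones(len(peaks), dtype=bool)
    qs, qe = peaks.linear()
    for cls in catalog.priority[:-1]:
        if not unassigned.any():
            break
        ms, me = catalog.class_regions[cls].merged_linear()
        hit = _overlap_flags_linear(qs, qe, ms, me)
        take = hit & unassigned
        labels[take] = cls
        unassigned &= ~hit
    return labels


def classify_peak(peak: GenomicInterval, catalog: FeatureCatalog) -> str:
    """Highest-priority feature class the peak overlaps by >=1 bp."""
    probe = RegionSet([peak], catalog.genome)
    return str(classify_peaks(probe, catalog)[0])


def summarize_classes(peaks: RegionSet, catalog: FeatureCatalog) -> dict[str, float]:
    """Proportion of peaks per feature class; proportions sum to 1."""
    if len(peaks) == 0:
        raise ValueError("cannot summarize an empty peak set")
    labels = classify_peaks(peaks, catalog)
    return {
        cls: float((labels == cls).sum()) / len(peaks) for cls in FEATURE_CLASSES
    }


def tss_signal_matrix(
    fragments: RegionSet,
    catalog: FeatureCatalog,
    flank: int = 500,
    bin_size: int = 10,
    skip_zeros: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Fragment coverage in bins spanning [tss - flank, tss + flank) per gene.

    Columns run 5' -> 3' in gene orientation (rows of minus-strand genes are
    flipped). Returns (matrix, gene_ids); all-zero rows are dropped when
    ``skip_zeros``. Genes whose full window does not fit inside the
    chromosome are skipped; no usable TSS at all is an error.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in catalog.genome.names:
        ivs = [iv for iv in fragments if iv.chrom == chrom]
        starts = np.sort(np.array([iv.start for iv in ivs], dtype=np.int64))
        ends = np.sort(np.array([iv.end for iv in ivs], dtype=np.int64))
        by_chrom[chrom] = (starts, ends)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for g in catalog.genes:
        if g.strand == "+":
            lo, hi = g.tss - flank, g.tss + flank
        else:
            # mirror of the + window around the TSS base (half-open bins)
            lo, hi = g.tss - flank + 1, g.tss + flank + 1
        if lo < 0 or hi > catalog.genome[g.chrom]:
            continue
        starts, ends = by_chrom[g.chrom]
        edges = lo + bin_size * np.arange(n_bins + 1, dtype=np.int64)
        # fragments overlapping bin [e0,e1) = total - #(end<=e0) - #(start>=e1)
        n = len(starts)
        n_end_before = np.searchsorted(ends, edges[:-1], side="right")
        n_start_after = n - np.searchsorted(starts, edges[1:], side="left")
        row = (n - n_end_before - n_start_after).astype(np.int64)
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    if not rows:
        raise ValueError("no gene has a full TSS window inside the genome")
    matrix = np.vstack(rows)
    if skip_zeros:
        keep = matrix.any(axis=1)
        matrix, ids = matrix[keep], [i for i, k in zip(ids, keep) if k]
    return matrix, ids


# -- simplified 8-column gene annotation dialect ----------------------------


def read_genes_tsv(path: str, genome: GenomeTable) -> list[GeneModel]:
    """Read the simplified gene annotation dialect.

    Columns: gene_id, chrom, strand, span_start, span_end, cds_start,
    cds_end, exon_blocks (comma-separated ``start-end`` pairs). UTR blocks
    are derived as exonic sequence outside [cds_start, cds_end), assigned to
    the 5' or 3' side by strand.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise RegionError(f"{path}:{lineno}: expected 8 columns")
            try:
                gene = build_gene(
                    gene_id=f[0],
                    chrom=f[1],
                    strand=f[2],
                    span_start=int(f[3]),
                    span_end=int(f[4]),
                    cds_start=int(f[5]),
                    cds_end=int(f[6]),
                    exon_blocks=[
                        (int(a), int(b))
                        for a, b in (p.split("-") for p in f[7].split(",") if p)
                    ],
                )
                genome.validate(gene.span)
            except (ValueError, RegionError) as exc:
                raise RegionError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    return genes


def build_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    span_start: int,
    span_end: int,
    cds_start: int,
    cds_end: int,
    exon_blocks: list[tuple[int, int]],
) -> GeneModel:
    """Construct a GeneModel, deriving CDS and UTR blocks from exons."""
    span = GenomicInterval(chrom, span_start, span_end)
    exons = [GenomicInterval(chrom, a, b) for a, b in sorted(exon_blocks)]
    cds: list[GenomicInterval] = []
    left_utr: list[GenomicInterval] = []
    right_utr: list[GenomicInterval] = []
    for ex in exons:
        c0, c1 = max(ex.start, cds_start), min(ex.end, cds_end)
        if c0 < c1:
            cds.append(GenomicInterval(chrom, c0, c1))
        if ex.start < min(ex.end, cds_start):
            left_utr.append(GenomicInterval(chrom, ex.start, min(ex.end, cds_start)))
        if max(ex.start, cds_end) < ex.end:
            right_utr.append(GenomicInterval(chrom, max(ex.start, cds_end), ex.end))
    utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        span=span,
        exon_blocks=exons,
        cds_blocks=cds,
        utr5_blocks=utr5,
        utr3_blocks=utr3,
    )


def write_genes_tsv(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cds_start = min((b.start for b in g.cds_blocks), default=g.span.start)
            cds_end = max((b.end for b in g.cds_blocks), default=g.span.start)
            exons = ",".join(f"{b.start}-{b.end}" for b in g.exon_blocks)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.span.start}\t{g.span.end}"
                f"\t{cds_start}\t{cds_end}\t{exons}\n"
            )
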