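"""Synthetic genomes, annotations, peaks, fragments and abundance tables.

Every pipeline stage can be exercised against data with known planted
structure. The generator emulates the statistical shape of the real sperm
MNase-seq study conditions: MN peak widths lognormal around ~270 bp and SN
around ~141 bp; fragment template lengths a two-component normal mixture
near 147 bp (mono-nucleosomal) and 95 bp (sub-nucleosomal); FPKM values
log-normal on the log2 scale spanning all four abundance classes; and
feature sets with plantable co-location enrichment.

Peak planting uses rejection sampling. A naive acceptance probability
proportional to rho(class) would make the realized fold change
rho / Z with Z = sum_c rho(c) * p(c) (p(c) = uniform-placement overlap
rate), not rho itself. To give rho the exact interpretation the
permutation FC estimates, the classes without a specified rho share a
common weight alpha chosen so that sum_c w(c) * p(c) = 1, with p(c)
estimated by Monte Carlo uniform placement. An infeasible rho map
(alpha <= 0, i.e. the boosted classes would demand more than the whole
placement mass) is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .annotation import build_gene
from .fragments import FragmentRecord
from .regions import (
    GenomeTable,
    GenomicInterval,
    GeneModel,
    RegionSet,
    _overlap_flags_linear,
    distances_to_set,
)

__all__ = [
    "SimulationConfig",
    "make_genome",
    "make_genes",
    "plant_peaks",
    "make_abundance",
    "make_fragments",
    "make_repeat_set",
    "lognormal_width_sampler",
]


@dataclass
class SimulationConfig:
    """Generator defaults: one 10-Mbp genome, 500 genes, 2,000 MN / 300 SN peaks."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (2_500_000, 2_500_000, 2_500_000, 2_500_000)
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (2_000, 12_000)
    exon_count_range: tuple[int, int] = (2, 8)
    promoter_len: int = 2_000
    n_peaks_mn: int = 2_000
    n_peaks_sn: int = 300
    mn_width_mean: float = 270.0
    mn_width_sigma: float = 0.35
    sn_width_mean: float = 141.0
    sn_width_sigma: float = 0.25
    min_peak_width: int = 50
    rho: dict[str, float] = field(default_factory=dict)
    fpkm_log2_mean: float = 0.0
    fpkm_log2_sd: float = 3.0
    beta: float = 1.0
    n_fragments: int = 20_000
    frag_mn_len: float = 147.0
    frag_sn_len: float = 95.0
    frag_len_sd: float = 10.0
    frag_mn_weight: float = 0.9

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("need at least one chromosome")
        if min(self.chrom_lengths) < 1 or self.n_genes < 1:
            raise ValueError("counts and lengths must be positive")
        if any(r < 0 for r in self.rho.values()):
            raise ValueError("rho must be >= 0")
        if not 0.0 <= self.frag_mn_weight <= 1.0:
            raise ValueError("mixture weight must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def make_genome(config: SimulationConfig) -> GenomeTable:
    """Chromosomes chr1..chrN with the configured lengths."""
    return GenomeTable(
        (f"chr{i + 1}", length) for i, length in enumerate(config.chrom_lengths)
    )


def _split_lengths(total: int, parts: int, minimum: int, rng: np.random.Generator):
    """Random positive integer composition of `total` into `parts` >= minimum."""
    if total < parts * minimum:
        raise ValueError("not enough room to split")
    spare = total - parts * minimum
    props = rng.dirichlet(np.ones(parts))
    extra = np.floor(props * spare).astype(int)
    extra[0] += spare - extra.sum()
    return extra + minimum


def make_genes(
    config: SimulationConfig, genome: GenomeTable, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Non-overlapping genes with exon/CDS/UTR structure on both strands.

    Genes are allotted to chromosomes proportionally to length and placed
    left to right with random inter-gene gaps of at least ``promoter_len``
    (so promoter windows never run into a neighboring gene body).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = genome.lengths
    alloc = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    while alloc.sum() < config.n_genes:
        alloc[int(np.argmax(lengths - alloc))] += 1
    lo, hi = config.gene_length_range
    min_gap = config.promoter_len + 100
    genes: list[GeneModel] = []
    gid = 0
    for ci, chrom in enumerate(genome.names):
        n = int(alloc[ci])
        if n == 0:
            continue
        spans = rng.integers(lo, hi + 1, size=n)
        needed = int(spans.sum()) + (n + 1) * min_gap
        if needed > genome[chrom]:
            raise ValueError(
                f"chromosome {chrom} too small for {n} genes of the requested size"
            )
        gaps = _split_lengths(genome[chrom] - int(spans.sum()), n + 1, min_gap, rng)
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start, end = pos, pos + int(spans[i])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _make_gene_structure(
                    f"gene{gid}", chrom, strand, start, end, config, rng
                )
            )
            gid += 1
    return genes


def _make_gene_structure(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GeneModel:
    """Alternating exon/intron blocks plus CDS bounds inside the span."""
    span_len = end - start
    k_lo, k_hi = config.exon_count_range
    max_exons = max(1, min(k_hi, span_len // 200))
    n_exons = int(rng.integers(min(k_lo, max_exons), max_exons + 1))
    n_parts = 2 * n_exons - 1
    parts = _split_lengths(span_len, n_parts, max(20, span_len // (4 * n_parts)), rng)
    edges = start + np.concatenate([[0], np.cumsum(parts)])
    exons = [(int(edges[2 * i]), int(edges[2 * i + 1])) for i in range(n_exons)]
    # CDS starts/ends inside the terminal exons, leaving room for UTRs
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    cds_start = int(rng.integers(first_s + 1, first_e)) if first_e - first_s > 1 else first_s
    cds_end = int(rng.integers(last_s + 1, last_e)) if last_e - last_s > 1 else last_e
    if cds_end <= cds_start:  # single-exon degenerate draw
        cds_start, cds_end = first_s, last_e
    return build_gene(
        gene_id, chrom, strand, start, end, cds_start, cds_end, exons
    )


def lognormal_width_sampler(mean: float, sigma: float, minimum: int = 50):
    """Sampler for peak widths: lognormal with the given arithmetic mean."""
    mu = np.log(mean) - sigma**2 / 2.0

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        w = np.round(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
        return np.maximum(w, minimum)

    return sample


def _classify_candidates(
    gs: np.ndarray,
    ge: np.ndarray,
    class_merged: list[tuple[str, np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Index of the first (highest-priority) class each candidate overlaps;
    -1 for background."""
    out = np.full(len(gs), -1, dtype=np.int64)
    unassigned = np.ones(len(gs), dtype=bool)
    for idx, (_, ms, me) in enumerate(class_merged):
        if not unassigned.any():
            break
        hit = _overlap_flags_linear(gs, ge, ms, me)
        out[hit & unassigned] = idx
        unassigned &= ~hit
    return out


def plant_peaks(
    n_peaks: int,
    width_sampler,
    genome: GenomeTable,
    class_regions: list[tuple[str, RegionSet]],
    rho: dict[str, float],
    rng: np.random.Generator,
    mc_samples: int = 4000,
    max_rounds: int = 2000,
    label: str = "peaks",
) -> RegionSet:
    """Place peaks so the expected overlap rate with class c is rho(c) x uniform.

    ``class_regions`` is an ordered (priority) list of labelled region sets;
    a candidate peak belongs to the first class it overlaps, else to the
    background. rho values default to 1 for unlisted classes; rho == 1
    everywhere reduces to uniform placement.
    """
    from .enrichment import shuffle_widths

    off = genome.offsets()
    chrom_off = np.array([off[n] for n in genome.names], dtype=np.int64)
    class_merged = [
        (name, *regions.merged_linear()) for name, regions in class_regions
    ]
    names = [name for name, _ in class_regions]
    unknown = set(rho) - set(names)
    if unknown:
        raise ValueError(f"rho given for unknown classes {sorted(unknown)}")

    effective_rho = np.array([rho.get(n, 1.0) for n in names])
    if np.allclose(effective_rho, 1.0):
        widths = width_sampler(n_peaks, rng)
        cidx, starts = shuffle_widths(widths, genome, rng)
        chrom_names = genome.names
        ivs = [
            GenomicInterval(chrom_names[c], int(s), int(s + w))
            for c, s, w in zip(cidx, starts, widths)
        ]
        return RegionSet(ivs, genome, label=label)

    # Monte Carlo estimate of the uniform-placement class rates p(c)
    mc = max(mc_samples, 2 * n_peaks)
    w_mc = width_sampler(mc, rng)
    cidx_mc, s_mc = shuffle_widths(w_mc, genome, rng)
    gs = chrom_off[cidx_mc] + s_mc
    cls_mc = _classify_candidates(gs, gs + w_mc, class_merged)
    p_hat = np.array([(cls_mc == i).mean() for i in range(len(names))])
    p_bg = (cls_mc == -1).mean()

    specified = np.array([n in rho for n in names])
    boosted_mass = float((effective_rho[specified] * p_hat[specified]).sum())
    free_mass = float(p_hat[~specified].sum() + p_bg)
    if free_mass <= 0 or boosted_mass >= 1.0:
        raise ValueError(
            f"infeasible rho map: planted classes demand overlap mass "
            f"{boosted_mass:.3f} >= 1"
        )
    alpha = (1.0 - boosted_mass) / free_mass
    weights = np.where(specified, effective_rho, alpha)
    w_bg = alpha
    w_max = max(float(weights.max()), w_bg)

    kept_chrom: list[np.ndarray] = []
    kept_start: list[np.ndarray] = []
    kept_width: list[np.ndarray] = []
    remaining = n_peaks
    for _ in range(max_rounds):
        if remaining <= 0:
            break
        batch = min(max(1024, 2 * remaining), 4 * n_peaks + 1024)
        w = width_sampler(batch, rng)
        cidx, starts = shuffle_widths(w, genome, rng)
        gs = chrom_off[cidx] + starts
        cls = _classify_candidates(gs, gs + w, class_merged)
        accept_p = np.where(cls >= 0, weights[np.clip(cls, 0, None)], w_bg) / w_max
        accept = rng.random(batch) < accept_p
        take = np.flatnonzero(accept)[:remaining]
        kept_chrom.append(cidx[take])
        kept_start.append(starts[take])
        kept_width.append(w[take])
        remaining -= len(take)
    if remaining > 0:
        raise ValueError("rejection sampling failed to place all peaks")
    cidx = np.concatenate(kept_chrom)
    starts = np.concatenate(kept_start)
    widths = np.concatenate(kept_width)
    chrom_names = genome.names
    ivs = [
        GenomicInterval(chrom_names[c], int(s), int(s + wd))
        for c, s, wd in zip(cidx, starts, widths)
    ]
    return RegionSet(ivs, genome, label=label)


def make_repeat_set(
    genome: GenomeTable,
    n: int,
    width: int,
    rng: np.random.Generator,
    exclude: RegionSet | None = None,
    margin: int = 300,
    label: str = "repeat",
    max_rounds: int = 1000,
) -> RegionSet:
    """Uniformly placed fixed-width repeat elements, optionally kept at least
    ``margin`` bp away from an exclusion set (e.g. gene spans + promoters,
    so repeat-targeted planting stays decoupled from gene-feature planting)."""
    from .enrichment import shuffle_widths

    off = genome.offsets()
    chrom_off = np.array([off[nm] for nm in genome.names], dtype=np.int64)
    if exclude is not None and len(exclude):
        ms, me = exclude.merged_linear()
        ms, me = ms - margin, me + margin
    else:
        ms = me = np.array([], dtype=np.int64)
    kept_c: list[np.ndarray] = []
    kept_s: list[np.ndarray] = []
    remaining = n
    for _ in range(max_rounds):
        if remaining <= 0:
            break
        batch = max(1024, 2 * remaining)
        w = np.full(batch, width, dtype=np.int64)
        cidx, starts = shuffle_widths(w, genome, rng)
        gs = chrom_off[cidx] + starts
        bad = _overlap_flags_linear(gs, gs + width, ms, me)
        take = np.flatnonzero(~bad)[:remaining]
        kept_c.append(cidx[take])
        kept_s.append(starts[take])
        remaining -= len(take)
    if remaining > 0:
        raise ValueError("could not place repeat elements outside the exclusion set")
    cidx = np.concatenate(kept_c)
    starts = np.concatenate(kept_s)
    names = genome.names
    ivs = [
        GenomicInterval(names[c], int(s), int(s + width))
        for c, s in zip(cidx, starts)
    ]
    return RegionSet(ivs, genome, label=label)


def make_abundance(
    config: SimulationConfig,
    genes: list[GeneModel],
    genome: GenomeTable,
    peaks: RegionSet,
    rng: np.random.Generator | None = None,
):
    """Log-normal FPKM table with a +beta log2 shift for peak-proximal genes.

    beta = 0 makes abundance independent of peak proximity (the null for
    the Fisher co-location calibration).
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spans = RegionSet([g.span for g in genes], genome)
    near = (
        distances_to_set(spans, peaks) < 5000
        if len(peaks)
        else np.zeros(len(genes), dtype=bool)
    )
    log2_fpkm = rng.normal(config.fpkm_log2_mean, config.fpkm_log2_sd, size=len(genes))
    log2_fpkm = log2_fpkm + config.beta * near
    fpkm = np.power(2.0, log2_fpkm)
    return pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "fpkm": fpkm}
    )


def make_fragments(
    config: SimulationConfig,
    peaks_mn: RegionSet,
    peaks_sn: RegionSet,
    genome: GenomeTable,
    rng: np.random.Generator | None = None,
) -> tuple[list[FragmentRecord], np.ndarray]:
    """Fragments centered inside peaks, template lengths from the 147/95 mixture.

    Returns (records, component_labels) with labels 'mn' / 'sn' giving the
    generating component of each fragment.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_fragments
    if n == 0:
        return [], np.array([], dtype=object)
    is_mn = rng.random(n) < config.frag_mn_weight
    if is_mn.any() and len(peaks_mn) == 0:
        raise ValueError("MN fragments requested but no MN peaks supplied")
    if (~is_mn).any() and len(peaks_sn) == 0:
        raise ValueError("SN fragments requested but no SN peaks supplied")
    means = np.where(is_mn, config.frag_mn_len, config.frag_sn_len)
    lengths = np.maximum(
        np.round(rng.normal(means, config.frag_len_sd)).astype(np.int64), 1
    )
    records: list[FragmentRecord] = []
    mn_ivs = peaks_mn.intervals
    sn_ivs = peaks_sn.intervals
    pick_mn = rng.integers(0, max(len(mn_ivs), 1), size=n)
    pick_sn = rng.integers(0, max(len(sn_ivs), 1), size=n)
    centers = rng.random(n)
    for i in range(n):
        iv = mn_ivs[pick_mn[i]] if is_mn[i] else sn_ivs[pick_sn[i]]
        center = iv.start + int(centers[i] * iv.width)
        length = int(lengths[i])
        chrom_len = genome[iv.chrom]
        start = max(0, min(center - length // 2, chrom_len - length))
        records.append(FragmentRecord(iv.chrom, start, start + length))
    labels = np.where(is_mn, "mn", "sn").astype(object)
    return records, labels
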