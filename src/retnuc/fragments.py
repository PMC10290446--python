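"""Insert-size partitioning of paired-end MNase fragments and coverage QC.

MNase digestion of sperm chromatin yields a mono-nucleosomal (MN) band of
~147 bp (DNA wrapped around a full histone octamer) and a sub-nucleosomal
(SN) band below ~110 bp. After alignment the two fractions are separated
purely on mapped template length: fragments of <= 110 bp go to the SN
fraction, 111-1000 bp to the MN fraction, anything longer is discarded.

Replicate agreement is assessed as the Pearson correlation of binned
genome-wide fragment coverage, with optional dropping of doubly-zero bins
and of robust outlier bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .regions import GenomeTable, GenomicInterval, RegionError, RegionSet

__all__ = [
    "FragmentRecord",
    "FractionPartition",
    "partition_fragments",
    "binned_coverage",
    "coverage_correlation",
    "read_fragments_tsv",
    "write_fragments_tsv",
]


@dataclass(frozen=True)
class FragmentRecord:
    """Mapped span of one properly-paired fragment (leftmost to rightmost mate)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise RegionError(
                f"invalid fragment {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def template_length(self) -> int:
        return self.end - self.start


@dataclass
class FractionPartition:
    """Disjoint, exhaustive split of fragments into SN / MN / discarded."""

    sn: RegionSet
    mn: RegionSet
    discarded: int

    @property
    def n_input(self) -> int:
        return len(self.sn) + len(self.mn) + self.discarded


def partition_fragments(
    records: list[FragmentRecord],
    genome: GenomeTable,
    sn_max: int = 110,
    mn_min: int = 111,
    mn_max: int = 1000,
) -> FractionPartition:
    """Assign every fragment to exactly one of SN / MN / discarded.

    SN: template length <= ``sn_max``; MN: ``mn_min`` <= length <= ``mn_max``;
    everything else is discarded. Counts are conserved.
    """
    if not sn_max < mn_min <= mn_max:
        raise ValueError(
            f"inverted bounds: require sn_max < mn_min <= mn_max, "
            f"got {sn_max}/{mn_min}/{mn_max}"
        )
    sn: list[GenomicInterval] = []
    mn: list[GenomicInterval] = []
    discarded = 0
    for rec in records:
        tl = rec.template_length
        iv = GenomicInterval(rec.chrom, rec.start, rec.end)
        if tl <= sn_max:
            sn.append(iv)
        elif mn_min <= tl <= mn_max:
            mn.append(iv)
        else:
            discarded += 1
    return FractionPartition(
        sn=RegionSet(sn, genome, label="SN"),
        mn=RegionSet(mn, genome, label="MN"),
        discarded=discarded,
    )


def binned_coverage(
    records: list[FragmentRecord], genome: GenomeTable, bin_size: int
) -> np.ndarray:
    """Per-bin fragment counts over the whole genome.

    Bins tile each chromosome (the last bin of a chromosome may be short);
    a fragment increments every bin it overlaps. Returns the concatenation
    of the per-chromosome bin vectors in genome order.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins_per = {n: -(-genome[n] // bin_size) for n in genome.names}
    bin_offsets: dict[str, int] = {}
    pos = 0
    for n in genome.names:
        bin_offsets[n] = pos
        pos += n_bins_per[n]
    total_bins = pos
    diff = np.zeros(total_bins + 1, dtype=np.int64)
    for rec in records:
        if rec.chrom not in bin_offsets:
            raise RegionError(f"fragment on unknown chromosome {rec.chrom!r}")
        first = bin_offsets[rec.chrom] + rec.start // bin_size
        last = bin_offsets[rec.chrom] + min(rec.end - 1, genome[rec.chrom] - 1) // bin_size
        diff[first] += 1
        diff[last + 1] -= 1
    return np.cumsum(diff[:-1])


def coverage_correlation(
    v1: np.ndarray,
    v2: np.ndarray,
    skip_zeros: bool = False,
    remove_outliers: bool = False,
    mad_k: float = 200.0,
) -> float:
    """Pearson r of two binned coverage vectors after optional filtering.

    ``skip_zeros`` drops bins where both vectors are zero; ``remove_outliers``
    drops bins where either value exceeds ``median + mad_k * MAD`` of its
    vector. Fewer than 2 surviving bins is an error.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("coverage vectors differ in length")
    keep = np.ones(len(v1), dtype=bool)
    if skip_zeros:
        keep &= (v1 != 0) | (v2 != 0)
    if remove_outliers:
        for v in (v1, v2):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            keep &= v <= med + mad_k * mad
    a, b = v1[keep], v2[keep]
    if len(a) < 2:
        raise ValueError("fewer than 2 bins survive filtering")
    r, _ = stats.pearsonr(a, b)
    return float(r)


def read_fragments_tsv(path: str, genome: GenomeTable) -> list[FragmentRecord]:
    """Read a simplified tabular fragment file: chrom, start, end per line."""
    records: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise RegionError(f"{path}:{lineno}: expected >=3 columns")
            try:
                rec = FragmentRecord(fields[0], int(fields[1]), int(fields[2]))
            except (ValueError, RegionError) as exc:
                raise RegionError(f"{path}:{lineno}: {exc}") from exc
            if rec.chrom not in genome or rec.end > genome[rec.chrom]:
                raise RegionError(f"{path}:{lineno}: fragment outside genome")
            records.append(rec)
    return records


def write_fragments_tsv(records: list[FragmentRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
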