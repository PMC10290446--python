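"""Genomic-interval data model and BED-dialect readers/writers.

All coordinates are 0-based, half-open (BED convention). Intervals are bound
to a :class:`GenomeTable`, which defines the chromosome name space and the
shuffle space for the permutation null. Chromosome name matching is exact
string matching; no ``chr``-prefix normalization is attempted.

The overlap counter and distance queries are implemented as vectorized
numpy ``searchsorted`` routines on a global linearization of the genome
(chromosomes concatenated end-to-end), because they sit inside the
1,000-iteration permutation loop and dominate its runtime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "RegionError",
    "GenomeTable",
    "GenomicInterval",
    "RegionSet",
    "GeneModel",
    "read_genome_table",
    "read_region_file",
    "write_region_file",
    "count_overlapping",
    "overlap_flags",
    "closest_distance",
    "distances_to_set",
]


class RegionError(ValueError):
    """Malformed interval data or a genome-binding violation."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise RegionError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise RegionError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


class GenomeTable:
    """Ordered chromosome-name -> length table defining the shuffle space."""

    def __init__(self, entries: Iterable[tuple[str, int]] = ()):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            self.add(name, length)

    def add(self, name: str, length: int) -> None:
        if name in self._lengths:
            raise RegionError(f"duplicate chromosome {name!r}")
        if length < 1:
            raise RegionError(f"chromosome {name!r} has non-positive length {length}")
        self._names.append(name)
        self._lengths[name] = int(length)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self._lengths[n] for n in self._names], dtype=np.int64)

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeTable):
            return NotImplemented
        return self._names == other._names and self._lengths == other._lengths

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum()) if self._names else 0

    def offsets(self) -> dict[str, int]:
        """Cumulative start offset of each chromosome in the linearized genome."""
        out: dict[str, int] = {}
        pos = 0
        for n in self._names:
            out[n] = pos
            pos += self._lengths[n]
        return out

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._lengths:
            raise RegionError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._lengths[iv.chrom]:
            raise RegionError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._lengths[iv.chrom]}"
            )


class RegionSet:
    """An ordered collection of intervals bound to a :class:`GenomeTable`.

    Intervals may overlap one another. The set caches a linearized
    (global-coordinate) representation for fast vectorized queries.
    """

    def __init__(
        self,
        intervals: Sequence[GenomicInterval],
        genome: GenomeTable,
        label: str = "",
    ):
        self.intervals = list(intervals)
        self.genome = genome
        self.label = label
        for iv in self.intervals:
            genome.validate(iv)
        self._linear: tuple[np.ndarray, np.ndarray] | None = None
        self._merged: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self.intervals], dtype=np.int64)

    # -- linearized views ---------------------------------------------------

    def linear(self) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) in global coordinates, input order preserved."""
        if self._linear is None:
            off = self.genome.offsets()
            starts = np.array(
                [off[iv.chrom] + iv.start for iv in self.intervals], dtype=np.int64
            )
            ends = np.array(
                [off[iv.chrom] + iv.end for iv in self.intervals], dtype=np.int64
            )
            self._linear = (starts, ends)
        return self._linear

    def merged_linear(self) -> tuple[np.ndarray, np.ndarray]:
        """Union of the intervals in global coordinates, sorted and merged.

        Merging across a chromosome boundary is harmless for overlap queries:
        the linearization is order-preserving and every query interval lies
        wholly within one chromosome.
        """
        if self._merged is None:
            starts, ends = self.linear()
            if len(starts) == 0:
                self._merged = (starts, ends)
                return self._merged
            order = np.argsort(starts, kind="stable")
            s, e = starts[order], ends[order]
            run_end = np.maximum.accumulate(e)
            # new run begins where a start exceeds the furthest end so far
            new_run = np.empty(len(s), dtype=bool)
            new_run[0] = True
            new_run[1:] = s[1:] > run_end[:-1]
            idx = np.flatnonzero(new_run)
            ms = s[idx]
            me = np.append(run_end[idx[1:] - 1], run_end[-1])
            self._merged = (ms, me)
        return self._merged


def _require_same_genome(a: RegionSet, b: RegionSet) -> None:
    if a.genome is not b.genome and a.genome != b.genome:
        raise RegionError("region sets are bound to different genomes")


def _overlap_flags_linear(
    qs: np.ndarray, qe: np.ndarray, ms: np.ndarray, me: np.ndarray
) -> np.ndarray:
    """Boolean per query interval: shares >=1 bp with the merged subject."""
    if len(ms) == 0 or len(qs) == 0:
        return np.zeros(len(qs), dtype=bool)
    idx = np.searchsorted(ms, qe, side="left")
    flags = idx > 0
    prev = np.clip(idx - 1, 0, None)
    flags &= me[prev] > qs
    return flags


def overlap_flags(query: RegionSet, subject: RegionSet) -> np.ndarray:
    """Per-query-interval boolean overlap flags against the subject union."""
    _require_same_genome(query, subject)
    qs, qe = query.linear()
    ms, me = subject.merged_linear()
    return _overlap_flags_linear(qs, qe, ms, me)


def count_overlapping(
    query: RegionSet, subject: RegionSet, mode: str = "per-query"
) -> int:
    """Number of query intervals overlapping the subject set by >=1 bp.

    ``mode="per-query"`` (default) counts each query interval at most once,
    so the count never exceeds ``len(query)``; ``mode="pairs"`` counts
    overlapping (query, subject) interval pairs instead.
    """
    _require_same_genome(query, subject)
    if mode == "per-query":
        return int(overlap_flags(query, subject).sum())
    if mode == "pairs":
        qs, qe = query.linear()
        ss, se = subject.linear()
        if len(ss) == 0 or len(qs) == 0:
            return 0
        # pairs overlapping q = #(subject.start < q.end) - #(subject.end <= q.start)
        ss_sorted = np.sort(ss)
        se_sorted = np.sort(se)
        n_start_before = np.searchsorted(ss_sorted, qe, side="left")
        n_end_before = np.searchsorted(se_sorted, qs, side="right")
        return int((n_start_before - n_end_before).sum())
    raise ValueError(f"unknown counting mode {mode!r}")


def distances_to_set(query: RegionSet, subject: RegionSet) -> np.ndarray:
    """Edge-gap distance from each query interval to the nearest subject interval.

    Overlapping or abutting intervals are at distance 0. Query intervals on a
    chromosome carrying no subject interval get ``inf``. Empty subject raises.
    """
    _require_same_genome(query, subject)
    if len(subject) == 0:
        raise RegionError("closest-distance query against an empty subject set")
    out = np.full(len(query), math.inf)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    arrs = {
        c: (
            np.sort(np.array([p[0] for p in lst], dtype=np.int64)),
            np.sort(np.array([p[1] for p in lst], dtype=np.int64)),
        )
        for c, lst in by_chrom.items()
    }
    for i, iv in enumerate(query.intervals):
        if iv.chrom not in arrs:
            continue
        ss, se = arrs[iv.chrom]
        # nearest subject start at/after the query end
        j = np.searchsorted(ss, iv.end, side="left")
        right_gap = ss[j] - iv.end if j < len(ss) else math.inf
        # nearest subject end at/before the query start
        k = np.searchsorted(se, iv.start, side="right")
        left_gap = iv.start - se[k - 1] if k > 0 else math.inf
        d = min(right_gap, left_gap)
        # overlap check: a subject with start < q.end and end > q.start exists
        n_start_before = np.searchsorted(ss, iv.end, side="left")
        n_end_before = np.searchsorted(se, iv.start, side="right")
        if n_start_before - n_end_before > 0:
            d = 0
        out[i] = max(d, 0)
    return out


def closest_distance(interval: GenomicInterval, subject: RegionSet) -> float:
    """Gap in bp between ``interval`` and the nearest subject interval.

    0 when they overlap or abut; ``inf`` when the subject has no interval on
    the interval's chromosome. Raises on an empty subject set.
    """
    probe = RegionSet([interval], subject.genome)
    return float(distances_to_set(probe, subject)[0])


# -- gene model -------------------------------------------------------------


def _check_blocks(
    blocks: Sequence[GenomicInterval], span: GenomicInterval, what: str
) -> None:
    prev_end = None
    for b in sorted(blocks, key=lambda x: x.start):
        if b.chrom != span.chrom or b.start < span.start or b.end > span.end:
            raise RegionError(f"{what} block outside gene span")
        if prev_end is not None and b.start < prev_end:
            raise RegionError(f"overlapping {what} blocks")
        prev_end = b.end


@dataclass
class GeneModel:
    """A protein-coding gene: span, strand, and exon/CDS/UTR block structure.

    The transcription start site is the 5'-most base of the span: ``span.start``
    on the + strand, ``span.end - 1`` on the - strand. Introns are derived as
    the span minus the exonic blocks.
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    exon_blocks: list[GenomicInterval] = field(default_factory=list)
    cds_blocks: list[GenomicInterval] = field(default_factory=list)
    utr5_blocks: list[GenomicInterval] = field(default_factory=list)
    utr3_blocks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise RegionError(f"gene {self.gene_id}: strand must be + or -")
        if self.span.chrom != self.chrom:
            raise RegionError(f"gene {self.gene_id}: span chromosome mismatch")
        for what, blocks in (
            ("exon", self.exon_blocks),
            ("cds", self.cds_blocks),
            ("utr5", self.utr5_blocks),
            ("utr3", self.utr3_blocks),
        ):
            _check_blocks(blocks, self.span, what)

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def introns(self) -> list[GenomicInterval]:
        """Span minus exonic blocks."""
        if not self.exon_blocks:
            return [self.span]
        out: list[GenomicInterval] = []
        pos = self.span.start
        for ex in sorted(self.exon_blocks, key=lambda b: b.start):
            if ex.start > pos:
                out.append(GenomicInterval(self.chrom, pos, ex.start))
            pos = max(pos, ex.end)
        if pos < self.span.end:
            out.append(GenomicInterval(self.chrom, pos, self.span.end))
        return out


# -- file I/O ---------------------------------------------------------------


def read_genome_table(path: str) -> GenomeTable:
    """Read a two-column ``chrom.sizes`` file (name, length)."""
    table = GenomeTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise RegionError(f"{path}:{lineno}: expected 2 columns")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise RegionError(f"{path}:{lineno}: non-integer length") from exc
            try:
                table.add(fields[0], length)
            except RegionError as exc:
                raise RegionError(f"{path}:{lineno}: {exc}") from exc
    return table


def read_region_file(path: str, genome: GenomeTable, label: str = "") -> RegionSet:
    """Read a BED3/BED6-dialect file (whitespace-delimited, '#' comments)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise RegionError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RegionError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, name=name, strand=strand)
                genome.validate(iv)
            except RegionError as exc:
                raise RegionError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return RegionSet(intervals, genome, label=label or path)


def write_region_file(regions: RegionSet, path: str) -> None:
    """Write BED6 with the interval width in the score column."""
    with open(path, "w") as fh:
        for i, iv in enumerate(regions):
            name = iv.name if iv.name is not None else f"{regions.label or 'region'}_{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.width}\t{iv.strand}\n"
            )
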