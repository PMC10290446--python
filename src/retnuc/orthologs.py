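"""Cross-species gene-set overlap via the hypergeometric test.

Workflow: select the genes lying near motif-bearing peaks (strictly less
than 500 bp by default), map them to orthologs in the target species, and
test whether the mapped set over-represents a reference gene list (e.g.,
genes with paternal preferential expression in the early embryo) with the
upper-tail hypergeometric probability P(X >= k) when drawing n genes from
a universe of N containing K reference genes.

The universe size N is a required explicit argument: the test is
meaningless without stating the gene universe, so it is never defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .regions import GeneModel, RegionSet, distances_to_set, RegionError

__all__ = [
    "OrthologMap",
    "OverlapTestInput",
    "genes_near_peaks",
    "map_orthologs",
    "hypergeometric_overlap",
    "read_ortholog_map",
]


class OrthologMap:
    """A possibly partial, possibly many-to-many source -> target gene map."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        self._by_source: dict[str, set[str]] = {}
        for src, tgt in pairs:
            if (src, tgt) in seen:
                raise ValueError(f"duplicate ortholog pair {(src, tgt)!r}")
            seen.add((src, tgt))
            self.pairs.append((src, tgt))
            self._by_source.setdefault(src, set()).add(tgt)

    def targets_of(self, source: str) -> set[str]:
        return set(self._by_source.get(source, ()))


def genes_near_peaks(
    genes: Sequence[GeneModel], peaks: RegionSet, max_dist: int = 500
) -> set[str]:
    """Gene ids whose span lies strictly below ``max_dist`` bp from a peak."""
    if len(peaks) == 0:
        raise RegionError("gene-proximity query against an empty peak set")
    if not genes:
        return set()
    spans = RegionSet([g.span for g in genes], peaks.genome)
    dist = distances_to_set(spans, peaks)
    return {g.gene_id for g, d in zip(genes, dist) if d < max_dist}


def map_orthologs(
    gene_ids: set[str], omap: OrthologMap
) -> tuple[set[str], int]:
    """Union of ortholog targets of the input ids; (targets, n_unmapped)."""
    targets: set[str] = set()
    dropped = 0
    for gid in gene_ids:
        t = omap.targets_of(gid)
        if t:
            targets |= t
        else:
            dropped += 1
    return targets, dropped


@dataclass(frozen=True)
class OverlapTestInput:
    """Hypergeometric test inputs: universe N, reference K, query n, overlap k."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) <= max(self.K, self.n) <= self.N):
            raise ValueError(
                f"invalid hypergeometric input N={self.N} K={self.K} "
                f"n={self.n} k={self.k}"
            )


def hypergeometric_overlap(inp: OverlapTestInput) -> float:
    """Exact upper-tail p = P(X >= k) for the overlap of two gene sets."""
    return float(stats.hypergeom.sf(inp.k - 1, inp.N, inp.K, inp.n))


def read_ortholog_map(path: str) -> OrthologMap:
    """Read a two-column source/target TSV."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((fields[0], fields[1]))
    return OrthologMap(pairs)
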