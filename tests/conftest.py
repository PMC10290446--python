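import numpy as np
import pytest

from retnuc import GenomeTable, GenomicInterval, RegionSet


@pytest.fixture
def toy_genome() -> GenomeTable:
    return GenomeTable([("chr1", 10_000), ("chr2", 5_000)])


@pytest.fixture
def sim_genome() -> GenomeTable:
    """The default synthetic scale: 10 Mbp over four chromosomes."""
    return GenomeTable([(f"chr{i}", 2_500_000) for i in range(1, 5)])


def random_region_set(
    genome: GenomeTable,
    n: int,
    rng: np.random.Generator,
    max_width: int = 500,
    label: str = "rand",
) -> RegionSet:
    """Uniform random intervals for brute-force comparisons."""
    names = genome.names
    lengths = genome.lengths
    ivs = []
    for _ in range(n):
        ci = int(rng.integers(0, len(names)))
        w = int(rng.integers(1, min(max_width, lengths[ci]) + 1))
        s = int(rng.integers(0, lengths[ci] - w + 1))
        ivs.append(GenomicInterval(names[ci], s, s + w))
    return RegionSet(ivs, genome, label=label)


def brute_force_overlap_count(query: RegionSet, subject: RegionSet) -> int:
    """O(n*m) oracle: query intervals sharing >=1 bp with any subject interval."""
    count = 0
    for q in query:
        for s in subject:
            if q.chrom == s.chrom and q.start < s.end and s.start < q.end:
                count += 1
                break
    return count
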