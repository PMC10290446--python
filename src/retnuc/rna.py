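"""Peak proximity vs gene-level RNA abundance.

Genes are binned by sperm RNA abundance (FPKM) into four classes:
absent [0, 1), low [1, 10), intermediate [10, 100) and high [100, inf).
A gene co-locates with a peak set when its span lies strictly less than
5 kb from the nearest peak (overlap => distance 0 => co-located). Each
expressed class is compared against the absent class with a two-tailed
Fisher exact test on the near/far 2x2 table, and the abundance profiles
of gene groups are compared with a Kruskal-Wallis test on
log2(FPKM + 1) values (the rank-based test is insensitive to the
pseudo-count; it only matters for the box-plot style summaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GeneModel, GenomeTable, RegionError, RegionSet, distances_to_set

__all__ = [
    "ABUNDANCE_CLASSES",
    "ContingencyTable2x2",
    "bin_abundance",
    "colocation_flag",
    "annotate_abundance",
    "build_table3",
    "fisher_class_vs_absent",
    "rna_colocation_report",
    "kruskal_wallis_log2",
    "abundance_summary",
    "read_abundance_tsv",
]

#: Half-open FPKM bins, in increasing abundance order.
ABUNDANCE_CLASSES = ("absent", "low", "intermediate", "high")
_BIN_EDGES = (1.0, 10.0, 100.0)


def bin_abundance(fpkm: float) -> str:
    """FPKM -> abundance class by the half-open bin edges 1 / 10 / 100."""
    if fpkm < 0:
        raise ValueError(f"negative FPKM {fpkm}")
    if fpkm < _BIN_EDGES[0]:
        return "absent"
    if fpkm < _BIN_EDGES[1]:
        return "low"
    if fpkm < _BIN_EDGES[2]:
        return "intermediate"
    return "high"


def colocation_flag(gene: GeneModel, peaks: RegionSet, max_dist: int = 5000) -> bool:
    """True iff the gene span lies strictly below ``max_dist`` bp from a peak."""
    if len(peaks) == 0:
        raise RegionError("co-location query against an empty peak set")
    probe = RegionSet([gene.span], peaks.genome)
    return bool(distances_to_set(probe, peaks)[0] < max_dist)


def annotate_abundance(
    fpkm: pd.DataFrame,
    genes: Sequence[GeneModel],
    genome: GenomeTable,
    peak_sets: dict[str, RegionSet],
    max_dist: int = 5000,
) -> pd.DataFrame:
    """Build the abundance table: class plus one near_<label> flag per peak set.

    ``fpkm`` needs columns gene_id and fpkm, one row per gene_id. Genes
    missing from the annotation are dropped.
    """
    if fpkm["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in abundance table")
    by_id = {g.gene_id: g for g in genes}
    df = fpkm[fpkm["gene_id"].isin(by_id)].copy().reset_index(drop=True)
    df["abundance_class"] = df["fpkm"].map(bin_abundance)
    spans = RegionSet([by_id[g].span for g in df["gene_id"]], genome)
    for label, peaks in peak_sets.items():
        if len(peaks) == 0:
            df[f"near_{label}"] = False
        else:
            df[f"near_{label}"] = distances_to_set(spans, peaks) < max_dist
    return df


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a,b) = focal class near/far, (c,d) = absent class near/far."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative contingency count")
        if min(self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d) == 0:
            raise ValueError("zero margin in contingency table")


def build_table3(
    abundance: pd.DataFrame, focal_class: str, near_col: str
) -> ContingencyTable2x2:
    """Near/far counts of the focal abundance class vs the absent class."""
    if focal_class == "absent" or focal_class not in ABUNDANCE_CLASSES:
        raise ValueError(f"focal class must be an expressed class, got {focal_class!r}")
    focal = abundance[abundance["abundance_class"] == focal_class]
    absent = abundance[abundance["abundance_class"] == "absent"]
    if len(focal) == 0 or len(absent) == 0:
        raise ValueError(f"empty gene class ({focal_class!r} or 'absent')")
    return ContingencyTable2x2(
        a=int(focal[near_col].sum()),
        b=int((~focal[near_col]).sum()),
        c=int(absent[near_col].sum()),
        d=int((~absent[near_col]).sum()),
    )


def fisher_class_vs_absent(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p by the probability-mass rule.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed table's
    (the convention of the standard exact-test implementations); computed
    in log space, safe for counts of order 1e4.
    """
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(p)


def rna_colocation_report(
    abundance: pd.DataFrame, near_cols: Sequence[str]
) -> pd.DataFrame:
    """Near/far counts and Fisher p per expressed class per peak set."""
    rows = []
    for near_col in near_cols:
        absent = abundance[abundance["abundance_class"] == "absent"]
        rows.append(
            {
                "fraction": near_col.removeprefix("near_"),
                "class": "absent",
                "near": int(absent[near_col].sum()),
                "far": int((~absent[near_col]).sum()),
                "p": np.nan,
            }
        )
        for cls in ABUNDANCE_CLASSES[1:]:
            tab = build_table3(abundance, cls, near_col)
            rows.append(
                {
                    "fraction": near_col.removeprefix("near_"),
                    "class": cls,
                    "near": tab.a,
                    "far": tab.b,
                    "p": fisher_class_vs_absent(tab),
                }
            )
    return pd.DataFrame(rows)


def kruskal_wallis_log2(
    groups: Sequence[Sequence[float]], pseudocount: float = 1.0
) -> tuple[float, float]:
    """Kruskal-Wallis H and p on log2(FPKM + pseudocount) per group.

    All values tied across all groups gives H = 0, p = 1 by convention.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    transformed = [np.log2(np.asarray(g, dtype=float) + pseudocount) for g in groups]
    pooled = np.concatenate(transformed)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*transformed)
    return float(h), float(p)


def abundance_summary(
    groups: dict[str, Sequence[float]], pseudocount: float = 1.0
) -> pd.DataFrame:
    """Box-plot style summary (n, median, quartiles of log2 abundance)."""
    rows = []
    for name, values in groups.items():
        x = np.log2(np.asarray(values, dtype=float) + pseudocount)
        rows.append(
            {
                "group": name,
                "n": len(x),
                "q1": float(np.percentile(x, 25)),
                "median": float(np.median(x)),
                "q3": float(np.percentile(x, 75)),
            }
        )
    return pd.DataFrame(rows)


def read_abundance_tsv(path: str) -> pd.DataFrame:
    """Read a gene_id / fpkm two-column TSV (header optional)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["gene_id", "fpkm"]
    )
    if df.iloc[0]["gene_id"] == "gene_id":  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df["fpkm"] = df["fpkm"].astype(float)
    if (df["fpkm"] < 0).any():
        raise ValueError(f"{path}: negative FPKM value")
    return df
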