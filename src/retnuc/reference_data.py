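"""Published summary statistics from the porcine sperm MNase-seq study.

These are the printed inputs for re-deriving the study's reported
statistics: observed overlap counts with their permutation-null means for
selected enrichment rows, and near/far gene counts per abundance class for
the RNA co-location contingency tables. They are inputs, not expected
outputs — the package recomputes fold changes and exact p-values from
them at run time.
"""

from __future__ import annotations

#: (fraction, feature) -> (observed overlap count, permutation mean).
PUBLISHED_ENRICHMENT: dict[tuple[str, str], tuple[int, float]] = {
    ("MN", "promoter"): (2793, 553.01),
    ("MN", "tss"): (914, 81.21),
    ("MN", "utr5"): (2070, 169.74),
    ("MN", "cds"): (3386, 814.82),
    ("MN", "intron"): (10527, 10168.04),
    ("MN", "utr3"): (576, 368.88),
    ("MN", "intergenic"): (12356, 14735.91),
    ("MN", "pirna"): (65, 14.54),
    ("MN", "gwas"): (189, 171.05),
    ("MN", "line"): (3826, 7889.53),
    ("MN", "sine"): (5892, 7182.70),
    ("MN", "human"): (5395, 215.71),
    ("SN", "utr3"): (27, 57.76),
    ("SN", "sine"): (1817, 979.63),
}

#: fraction -> abundance class -> (genes near a peak, genes far from a peak).
#: "near" means the gene span lies less than 5 kb from a peak of the fraction.
PUBLISHED_RNA_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "MN": {
        "absent": (4083, 8042),
        "low": (2774, 3040),
        "intermediate": (1857, 1664),
        "high": (296, 302),
    },
    "SN": {
        "absent": (644, 11481),
        "low": (504, 5310),
        "intermediate": (455, 3066),
        "high": (60, 538),
    },
}

#: Cross-species gene-set overlap reported for the Znf263-motif analysis:
#: k of n query orthologs fell in the K-gene reference list. The universe N
#: behind the printed p was not stated and must be supplied explicitly.
PUBLISHED_ZNF263_OVERLAP = {"K": 514, "n": 3288, "k": 92}
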