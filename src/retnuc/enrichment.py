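"""Width-preserving permutation null, empirical p, fold change, labels.

The null model randomizes the genomic locations of a region set while
keeping its width multiset fixed: each interval is re-placed uniformly at
random wholly inside a chromosome, with the chromosome drawn with
probability proportional to its length (genome-wide placement; a
same-chromosome mode is available). Shuffled intervals may overlap one
another and any genome position.

The observed overlap count with a subject set is compared with the counts
from ``n_perms`` independent randomizations. The empirical two-sided p is
the proportion of permutations whose count deviates from the permutation
mean at least as much as the observed count (ties count toward p). Fold
change is observed / permutation mean. A comparison is labelled enriched
when p < 0.001 and FC >= 1.5, depleted when p < 0.001 and FC <= 0.66.

The reported SE column is the standard deviation of the permutation
counts; the printed summary-table magnitudes are consistent with this
definition (switch to ``sd / sqrt(n)`` via ``se_as_sd=False``).

Reproducibility: one root seed; permutation i draws from spawned
substream i, so results do not depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .regions import GenomeTable, GenomicInterval, RegionSet, count_overlapping

__all__ = [
    "ShuffleConfig",
    "EnrichmentResult",
    "shuffle_regions",
    "shuffle_widths",
    "compute_empirical_p",
    "format_p",
    "compute_fold_change",
    "classify_enrichment",
    "permutation_test",
    "enrichment_report",
]


@dataclass
class ShuffleConfig:
    """Randomization settings for the permutation test."""

    n_perms: int = 1000
    seed: int = 0
    placement: str = "genome-wide"  # or "same-chromosome"
    max_tries: int = 1000
    p_thresh: float = 0.001
    fc_up: float = 1.5
    fc_down: float = 0.66
    counting_mode: str = "per-query"

    def __post_init__(self) -> None:
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")
        if self.placement not in ("genome-wide", "same-chromosome"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class EnrichmentResult:
    """One row of the enrichment summary (the published-table schema)."""

    feature: str
    observed: int
    perm_counts: np.ndarray = field(repr=False)
    p_emp: float = 0.0
    fc: float | None = None
    label: str = "none"

    @property
    def perm_min(self) -> int:
        return int(self.perm_counts.min())

    @property
    def perm_max(self) -> int:
        return int(self.perm_counts.max())

    @property
    def perm_mean(self) -> float:
        return float(self.perm_counts.mean())

    @property
    def perm_se(self) -> float:
        """Standard deviation of the permutation counts (reported as SE)."""
        return float(self.perm_counts.std(ddof=1)) if len(self.perm_counts) > 1 else 0.0

    @property
    def p_formatted(self) -> str:
        return format_p(self.p_emp, len(self.perm_counts))


def shuffle_widths(
    widths: np.ndarray,
    genome: GenomeTable,
    rng: np.random.Generator,
    placement_chroms: np.ndarray | None = None,
    max_tries: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Place intervals of the given widths uniformly at random in the genome.

    Returns (chrom_index, start) arrays. Chromosomes are drawn with
    probability proportional to length; an interval that does not fit the
    drawn chromosome is redrawn, up to ``max_tries`` rounds. When
    ``placement_chroms`` is given (same-chromosome mode) the chromosome of
    each interval is fixed and only the start is randomized.
    """
    widths = np.asarray(widths, dtype=np.int64)
    lengths = genome.lengths
    if len(lengths) == 0:
        raise ValueError("cannot shuffle on an empty genome")
    if widths.size and int(widths.max()) > int(lengths.max()):
        raise ValueError(
            f"interval of width {int(widths.max())} exceeds every chromosome"
        )
    n = len(widths)
    if placement_chroms is not None:
        chrom_idx = np.asarray(placement_chroms, dtype=np.int64)
        if np.any(widths > lengths[chrom_idx]):
            raise ValueError("interval wider than its own chromosome")
        span = lengths[chrom_idx] - widths
        starts = rng.integers(0, span + 1)
        return chrom_idx, starts
    probs = lengths / lengths.sum()
    chrom_idx = np.empty(n, dtype=np.int64)
    starts = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    for _ in range(max_tries):
        if todo.size == 0:
            break
        draw = rng.choice(len(lengths), size=todo.size, p=probs)
        fits = widths[todo] <= lengths[draw]
        ok = todo[fits]
        chrom_idx[ok] = draw[fits]
        starts[ok] = rng.integers(
            0, lengths[draw[fits]] - widths[ok] + 1
        )
        todo = todo[~fits]
    if todo.size:
        raise ValueError("could not place all intervals within max_tries")
    return chrom_idx, starts


def shuffle_regions(
    regions: RegionSet,
    genome: GenomeTable,
    rng: np.random.Generator,
    placement: str = "genome-wide",
    max_tries: int = 1000,
) -> RegionSet:
    """Width-preserving randomization of a region set (see module docstring)."""
    widths = regions.widths()
    if placement == "same-chromosome":
        name_to_idx = {n: i for i, n in enumerate(genome.names)}
        fixed = np.array([name_to_idx[iv.chrom] for iv in regions], dtype=np.int64)
        chrom_idx, starts = shuffle_widths(
            widths, genome, rng, placement_chroms=fixed, max_tries=max_tries
        )
    else:
        chrom_idx, starts = shuffle_widths(widths, genome, rng, max_tries=max_tries)
    names = genome.names
    ivs = [
        GenomicInterval(names[c], int(s), int(s + w))
        for c, s, w in zip(chrom_idx, starts, widths)
    ]
    return RegionSet(ivs, genome, label=f"shuffled:{regions.label}")


def compute_empirical_p(observed: float, perm_counts: np.ndarray) -> float:
    """Two-sided empirical p: share of permutations deviating from the
    permutation mean at least as much as the observed count (ties included)."""
    perm_counts = np.asarray(perm_counts, dtype=float)
    if perm_counts.size == 0:
        raise ValueError("perm_counts must be non-empty")
    mean = perm_counts.mean()
    dev_obs = abs(observed - mean)
    return float(np.mean(np.abs(perm_counts - mean) >= dev_obs))


def format_p(p: float, n_perms: int) -> str:
    """A p of 0 is below the permutation resolution: print '<1/n_perms'."""
    if p == 0.0:
        return f"<{1.0 / n_perms:g}"
    return f"{p:g}"


def compute_fold_change(observed: float, perm_mean: float) -> float | None:
    """Observed overlap count divided by the permutation-mean count."""
    if perm_mean == 0:
        warnings.warn(
            "permutation mean is 0; fold change is undefined", stacklevel=2
        )
        return None
    return observed / perm_mean


def classify_enrichment(
    p_emp: float,
    fc: float | None,
    p_thresh: float = 0.001,
    fc_up: float = 1.5,
    fc_down: float = 0.66,
) -> str:
    """'enriched' / 'depleted' / 'none' by the p-and-FC double threshold."""
    if not (fc_down < fc_up) or p_thresh <= 0:
        raise ValueError("invalid thresholds")
    if fc is None or p_emp >= p_thresh:
        return "none"
    if fc >= fc_up:
        return "enriched"
    if fc <= fc_down:
        return "depleted"
    return "none"


def permutation_test(
    query: RegionSet,
    subject: RegionSet,
    genome: GenomeTable,
    config: ShuffleConfig,
) -> EnrichmentResult:
    """Full permutation co-location test of ``query`` against ``subject``."""
    observed = count_overlapping(query, subject, mode=config.counting_mode)
    widths = query.widths()
    name_to_idx = {n: i for i, n in enumerate(genome.names)}
    fixed = (
        np.array([name_to_idx[iv.chrom] for iv in query], dtype=np.int64)
        if config.placement == "same-chromosome"
        else None
    )
    ms, me = subject.merged_linear()
    off = genome.offsets()
    chrom_off = np.array([off[n] for n in genome.names], dtype=np.int64)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_perms)
    perm_counts = np.empty(config.n_perms, dtype=np.int64)
    from .regions import _overlap_flags_linear

    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        chrom_idx, starts = shuffle_widths(
            widths, genome, rng, placement_chroms=fixed, max_tries=config.max_tries
        )
        gs = chrom_off[chrom_idx] + starts
        ge = gs + widths
        if config.counting_mode == "per-query":
            perm_counts[i] = int(_overlap_flags_linear(gs, ge, ms, me).sum())
        else:
            sls, sle = subject.linear()
            n_start_before = np.searchsorted(np.sort(sls), ge, side="left")
            n_end_before = np.searchsorted(np.sort(sle), gs, side="right")
            perm_counts[i] = int((n_start_before - n_end_before).sum())
    p_emp = compute_empirical_p(observed, perm_counts)
    fc = compute_fold_change(observed, float(perm_counts.mean()))
    label = classify_enrichment(
        p_emp, fc, p_thresh=config.p_thresh, fc_up=config.fc_up, fc_down=config.fc_down
    )
    return EnrichmentResult(
        feature=subject.label,
        observed=observed,
        perm_counts=perm_counts,
        p_emp=p_emp,
        fc=fc,
        label=label,
    )


def enrichment_report(
    query: RegionSet,
    subjects: dict[str, RegionSet],
    genome: GenomeTable,
    config: ShuffleConfig,
):
    """One permutation test per subject set; returns a pandas DataFrame
    in the summary-table schema (Feature, Real, Min, Max, Mean, SE, P, FC,
    Label) plus raw full-precision columns."""
    import pandas as pd

    rows = []
    for name, subject in subjects.items():
        res = permutation_test(query, subject, genome, config)
        rows.append(
            {
                "Feature": name,
                "Real": res.observed,
                "Min": res.perm_min,
                "Max": res.perm_max,
                "Mean": round(res.perm_mean, 2),
                "SE": round(res.perm_se, 2),
                "P": res.p_formatted,
                "FC": round(res.fc, 2) if res.fc is not None else float("nan"),
                "Label": res.label,
                "P_raw": res.p_emp,
                "FC_raw": res.fc if res.fc is not None else float("nan"),
                "Mean_raw": res.perm_mean,
                "SE_raw": res.perm_se,
            }
        )
    return pd.DataFrame(rows)
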