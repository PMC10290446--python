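"""End-to-end orchestration: inputs -> enrichment / RNA / annotation reports.

``run_full_analysis`` wires the stages together for both real (file-based)
and synthetic inputs and writes:

* ``class_proportions.tsv``   — peak share per gene-feature class, per fraction
* ``enrichment_MN.tsv`` / ``enrichment_SN.tsv`` — permutation co-location
  summaries (Feature, Real, Min, Max, Mean, SE, P, FC, Label + raw columns)
* ``rna_colocation.tsv``      — near/far counts and Fisher p per abundance class
* ``tss_matrix_MN.tsv`` / ``tss_matrix_SN.tsv`` — TSS-centered coverage
  (only when fragments are supplied)
* ``run_log.json``            — config echo and package version

Outputs are deterministic for a given seed: rerunning with the same config
produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .annotation import (
    build_feature_catalog,
    read_genes_tsv,
    summarize_classes,
    tss_signal_matrix,
)
from .enrichment import ShuffleConfig, enrichment_report
from .fragments import partition_fragments, read_fragments_tsv
from .regions import RegionSet, read_genome_table, read_region_file
from .rna import annotate_abundance, read_abundance_tsv, rna_colocation_report


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and offending input."""


@dataclass
class RunConfig:
    """Paths and thresholds for a full analysis run."""

    genome: str
    genes: str
    peaks_mn: str
    peaks_sn: str
    fpkm: str | None = None
    fragments: str | None = None
    subjects: dict[str, str] = field(default_factory=dict)
    outdir: str = "retnuc_out"
    n_perms: int = 1000
    seed: int = 0
    p_thresh: float = 0.001
    fc_up: float = 1.5
    fc_down: float = 0.66
    promoter_len: int = 2000
    rna_max_dist: int = 5000
    sn_max: int = 110
    mn_min: int = 111
    mn_max: int = 1000
    tss_flank: int = 500
    tss_bin: int = 10

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str, detail: str):
    """Context annotating any exception with the failing stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed on {detail}: {exc}") from exc

    return _Ctx()


def run_full_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the whole analysis; returns the report tables and writes TSVs."""
    os.makedirs(config.outdir, exist_ok=True)
    out: dict[str, pd.DataFrame] = {}

    with _stage("load-genome", config.genome):
        genome = read_genome_table(config.genome)
    with _stage("load-genes", config.genes):
        genes = read_genes_tsv(config.genes, genome)
    with _stage("load-peaks", config.peaks_mn):
        peaks = {
            "MN": read_region_file(config.peaks_mn, genome, label="MN"),
            "SN": read_region_file(config.peaks_sn, genome, label="SN"),
        }
    with _stage("build-catalog", config.genes):
        catalog = build_feature_catalog(genes, genome, promoter_len=config.promoter_len)
        feature_sets = dict(catalog.class_regions)
        feature_sets["INTERGENIC"] = catalog.intergenic()
    with _stage("load-subjects", ", ".join(config.subjects) or "none"):
        subject_sets = {
            name: read_region_file(path, genome, label=name)
            for name, path in config.subjects.items()
        }

    # peak share per gene-feature class
    with _stage("classify-peaks", "peak sets"):
        prop_rows = []
        for frac, pk in peaks.items():
            props = summarize_classes(pk, catalog)
            for cls, p in props.items():
                prop_rows.append({"fraction": frac, "class": cls, "proportion": p})
        out["class_proportions"] = pd.DataFrame(prop_rows)

    # permutation enrichment per fraction, gene features first then subjects
    for frac, pk in peaks.items():
        with _stage("enrichment", f"{frac} peaks"):
            cfg = ShuffleConfig(
                n_perms=config.n_perms,
                seed=config.seed,
                p_thresh=config.p_thresh,
                fc_up=config.fc_up,
                fc_down=config.fc_down,
            )
            subjects = {**feature_sets, **subject_sets}
            out[f"enrichment_{frac}"] = enrichment_report(pk, subjects, genome, cfg)

    # RNA abundance co-location
    if config.fpkm is not None:
        with _stage("rna-colocation", config.fpkm):
            fpkm = read_abundance_tsv(config.fpkm)
            abundance = annotate_abundance(
                fpkm, genes, genome, peaks, max_dist=config.rna_max_dist
            )
            out["rna_colocation"] = rna_colocation_report(
                abundance, [f"near_{f}" for f in peaks]
            )

    # TSS-centered signal of each fragment fraction
    if config.fragments is not None:
        with _stage("tss-matrix", config.fragments):
            records = read_fragments_tsv(config.fragments, genome)
            part = partition_fragments(
                records, genome, config.sn_max, config.mn_min, config.mn_max
            )
            for frac, frag_set in (("MN", part.mn), ("SN", part.sn)):
                matrix, ids = tss_signal_matrix(
                    frag_set, catalog, flank=config.tss_flank, bin_size=config.tss_bin
                )
                df = pd.DataFrame(matrix, index=pd.Index(ids, name="gene_id"))
                out[f"tss_matrix_{frac}"] = df

    _write_outputs(out, config)
    return out


def _write_outputs(tables: dict[str, pd.DataFrame], config: RunConfig) -> None:
    for name, df in tables.items():
        path = os.path.join(config.outdir, f"{name}.tsv")
        df.to_csv(
            path,
            sep="\t",
            index=name.startswith("tss_matrix"),
            float_format="%.6g",
        )
    log = {"version": __version__, "config": config.to_dict()}
    with open(os.path.join(config.outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_scenario(config, outdir: str) -> dict[str, str]:
    """Generate a complete synthetic input directory from a SimulationConfig.

    Writes chrom.sizes, genes.tsv, peaks_mn.bed, peaks_sn.bed,
    fragments.tsv, fpkm.tsv and sim_config.json; returns the path map.
    """
    import numpy as np

    from .annotation import build_feature_catalog, write_genes_tsv
    from .fragments import write_fragments_tsv
    from .regions import write_region_file
    from .simulate import (
        lognormal_width_sampler,
        make_abundance,
        make_fragments,
        make_genes,
        make_genome,
        plant_peaks,
    )

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = make_genome(config)
    genes = make_genes(config, genome, rng)
    catalog = build_feature_catalog(genes, genome, promoter_len=config.promoter_len)
    class_regions = [
        (c, catalog.class_regions[c]) for c in catalog.priority[:-1]
    ]
    peaks_mn = plant_peaks(
        config.n_peaks_mn,
        lognormal_width_sampler(
            config.mn_width_mean, config.mn_width_sigma, config.min_peak_width
        ),
        genome,
        class_regions,
        config.rho,
        rng,
        label="MN",
    )
    peaks_sn = plant_peaks(
        config.n_peaks_sn,
        lognormal_width_sampler(
            config.sn_width_mean, config.sn_width_sigma, config.min_peak_width
        ),
        genome,
        class_regions,
        {},
        rng,
        label="SN",
    )
    abundance = make_abundance(config, genes, genome, peaks_mn, rng)
    fragments, _ = make_fragments(config, peaks_mn, peaks_sn, genome, rng)

    paths = {
        "genome": os.path.join(outdir, "chrom.sizes"),
        "genes": os.path.join(outdir, "genes.tsv"),
        "peaks_mn": os.path.join(outdir, "peaks_mn.bed"),
        "peaks_sn": os.path.join(outdir, "peaks_sn.bed"),
        "fpkm": os.path.join(outdir, "fpkm.tsv"),
        "fragments": os.path.join(outdir, "fragments.tsv"),
    }
    with open(paths["genome"], "w") as fh:
        for name in genome.names:
            fh.write(f"{name}\t{genome[name]}\n")
    write_genes_tsv(genes, paths["genes"])
    write_region_file(peaks_mn, paths["peaks_mn"])
    write_region_file(peaks_sn, paths["peaks_sn"])
    abundance.to_csv(paths["fpkm"], sep="\t", index=False, header=False)
    write_fragments_tsv(fragments, paths["fragments"])
    with open(os.path.join(outdir, "sim_config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
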