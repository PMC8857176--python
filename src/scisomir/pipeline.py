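"""End-to-end pipeline: processing -> annotation -> counting -> filtering ->
profiling -> (optional) deduplication and target analysis.

A run is fully described by a :class:`PipelineConfig`; given identical config
and seed, two runs produce byte-identical outputs and manifests. The
manifest (JSON) echoes the configuration, library versions and a SHA-256
digest of every output file, and suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, io
from .annotate import AlignmentParams, annotate_frame
from .errors import ConfigError
from .processing import dedup_umis, process_cell, processed_to_frame
from .profiles import (
    category_proportions,
    cell_similarity_clustering,
    count_features,
    dedup_shift_report,
    filter_cells,
    length_distribution,
    positional_profile,
)
from .reference import read_reference
from .simulate import DEFAULT_ADAPTER
from .targets import ks_results_frame, run_target_analysis

logger = logging.getLogger("scisomir")


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters for a full run."""

    reads_dir: str
    reference_fasta: str
    mature_gff3: str
    out_dir: str
    targets_tsv: str | None = None
    mrna_tsv: str | None = None
    # processing
    umi_length: int = 8
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 1
    max_error_rate: float = 0.1
    min_len: int = 15
    # annotation
    max_sub: int = 1
    max_trim: int = 3
    max_add: int = 3
    # quantification
    min_cell_reads: int = 1000
    dedup_mode: str = "exact"
    # target analysis
    alpha: float = 0.05
    top_k_mirnas: int = 6
    min_noncanonical_share: float = 0.1
    mirna_normalization: str = "cpm"
    mrna_normalization: str = "log1p_cpm"
    seed: int = 0

    def validate_paths(self) -> None:
        for label in ("reads_dir", "reference_fasta", "mature_gff3", "targets_tsv",
                      "mrna_tsv"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{label} does not exist: {value}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = io.load_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        io.dump_yaml(self.to_dict(), path)


@dataclass
class PipelineResult:
    out_dir: Path
    annotations: pd.DataFrame
    counts_mirna: object
    drop_stats: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``cfg.out_dir``."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    logger.info("reading reference %s", cfg.reference_fasta)
    ref = read_reference(cfg.reference_fasta, cfg.mature_gff3)
    raw = io.read_fastq_dir(cfg.reads_dir)

    # --- processing ----------------------------------------------------
    processed = {}
    stats_rows = []
    for cell in sorted(raw):
        reads, stats = process_cell(
            raw[cell], cell_id=cell, umi_length=cfg.umi_length,
            adapter=cfg.adapter or None, min_overlap=cfg.min_overlap,
            max_error_rate=cfg.max_error_rate, min_len=cfg.min_len,
        )
        processed[cell] = reads
        stats_rows.append(stats.to_row())
    drop_stats = pd.DataFrame(stats_rows)
    drop_stats.to_csv(out / "drop_stats.tsv", sep="\t", index=False)
    logger.info("processed %d cells, %d surviving reads",
                len(processed), int(drop_stats["survivors"].sum()))

    # --- annotation ----------------------------------------------------
    params = AlignmentParams(cfg.max_sub, cfg.max_trim, cfg.max_add)
    ann, unmapped = annotate_frame(processed_to_frame(processed), ref, params)
    io.write_annotations(ann, out / "annotations.tsv")
    unmapped.to_csv(out / "mapping_stats.tsv", sep="\t", index=False)

    # --- counting and cell filtering -----------------------------------
    counts_mirna = count_features(ann, mode="reads", level="mirna")
    keep = filter_cells(counts_mirna, cfg.min_cell_reads).df.index
    ann = ann[ann["cell"].isin(keep)].reset_index(drop=True)
    counts_mirna = count_features(ann, mode="reads", level="mirna")
    io.write_matrix(counts_mirna.df, out / "counts_mirna_reads.tsv")
    io.write_matrix(count_features(ann, "reads", "isomir").df,
                    out / "counts_isomir_reads.tsv")
    io.write_matrix(count_features(ann, "reads", "category").df,
                    out / "counts_category_reads.tsv")
    logger.info("%d cells pass the %d-read filter", len(keep), cfg.min_cell_reads)

    # --- profiles -------------------------------------------------------
    cat_prop = category_proportions(ann)
    io.write_matrix(cat_prop, out / "category_proportions.tsv")
    io.write_matrix(positional_profile(ann), out / "positional_profile_all.tsv",
                    index_label="group")
    io.write_matrix(positional_profile(ann, group_by="mature"),
                    out / "positional_profile_per_mirna.tsv", index_label="group")
    length_distribution(ann).to_csv(out / "length_distribution.tsv", sep="\t")
    length_distribution(ann, scope="canonical_only").to_csv(
        out / "length_distribution_canonical.tsv", sep="\t")

    if len(counts_mirna.df) >= 2:
        clust = cell_similarity_clustering(counts_mirna)
        io.write_matrix(clust.correlation, out / "cell_spearman.tsv")
        (out / "cell_leaf_order.txt").write_text("\n".join(clust.leaf_order) + "\n")

    # --- UMI deduplication ---------------------------------------------
    if cfg.umi_length > 0:
        dedup = dedup_umis(ann, mode=cfg.dedup_mode)
        io.write_matrix(count_features(dedup, "umis", "mirna").df,
                        out / "counts_mirna_umis.tsv")
        io.write_matrix(count_features(dedup, "umis", "category").df,
                        out / "counts_category_umis.tsv")
        post_prop = category_proportions(dedup)
        io.write_matrix(post_prop, out / "category_proportions_dedup.tsv")
        _, shift = dedup_shift_report(cat_prop, post_prop)
        shift.rename("mean_delta").to_csv(out / "dedup_shift.tsv", sep="\t")
        logger.info("dedup: %d reads -> %d molecules", len(ann), len(dedup))

    # --- target analysis ------------------------------------------------
    if cfg.targets_tsv and cfg.mrna_tsv:
        mrna = io.read_matrix(cfg.mrna_tsv)
        target_table = io.read_target_table(cfg.targets_tsv)
        results, ecdf = run_target_analysis(
            ann, mrna, target_table,
            top_k_mirnas=cfg.top_k_mirnas,
            min_noncanonical_share=cfg.min_noncanonical_share,
            alpha=cfg.alpha,
            mirna_normalization=cfg.mirna_normalization,
            mrna_normalization=cfg.mrna_normalization,
        )
        ks_results_frame(results).to_csv(out / "ks_results.tsv", sep="\t", index=False)
        ecdf.to_csv(out / "ecdf.tsv", sep="\t", index=False)
        logger.info("target analysis: %d miRNA x category tests",
                    len(results))

    # --- manifest -------------------------------------------------------
    outputs = sorted(
        p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "scisomir_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_cells_input": len(raw),
        "n_cells_kept": int(len(keep)),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        out_dir=out, annotations=ann, counts_mirna=counts_mirna,
        drop_stats=drop_stats, manifest=manifest,
    )


def run_demo(out_dir, seed: int = 0, n_cells: int = 10, reads_per_cell: int = 1500,
             n_precursors: int = 8) -> PipelineResult:
    """Simulate a small ground-truthed dataset and run the full pipeline on it.

    Writes the simulated inputs under ``<out_dir>/sim`` and the pipeline
    artifacts under ``<out_dir>/results``.
    """
    from .simulate import (SimulationConfig, make_reference, simulate_cells,
                           simulate_mrna_coupled)

    out = Path(out_dir)
    sim_dir = out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    ref = make_reference(n_precursors, seed=seed)
    ref.write(sim_dir / "precursors.fasta", sim_dir / "mature.gff3")
    cfg = SimulationConfig(n_cells=n_cells, reads_per_cell=reads_per_cell, seed=seed)
    sim = simulate_cells(ref, cfg)
    sim.write_fastq_dir(sim_dir / "fastq")
    mrna, table = simulate_mrna_coupled(
        sim.truth, n_genes=300, n_targets_per_mirna=25, effect_r=-0.6,
        seed=seed, mirnas=None,
    )
    io.write_matrix(mrna, sim_dir / "mrna.tsv", index_label="gene")
    io.write_target_table(table, sim_dir / "targets.tsv")
    sim.truth.molecules.to_csv(sim_dir / "ground_truth.tsv", sep="\t", index=False)

    pipe_cfg = PipelineConfig(
        reads_dir=str(sim_dir / "fastq"),
        reference_fasta=str(sim_dir / "precursors.fasta"),
        mature_gff3=str(sim_dir / "mature.gff3"),
        out_dir=str(out / "results"),
        targets_tsv=str(sim_dir / "targets.tsv"),
        mrna_tsv=str(sim_dir / "mrna.tsv"),
        umi_length=cfg.umi_length,
        adapter=cfg.adapter,
        seed=seed,
    )
    return run_pipeline(pipe_cfg)
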