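"""End-to-end orchestration: ingestion -> embedding -> encoder -> clustering
-> enrichment, with a reproducible report bundle.

A run is described by one :class:`RunConfig` holding either real input paths
(cohort CSV, Gene2Vec embedding, phenotype annotations, term DB, ASD list) or
a synthetic-generator config, plus the stage parameters and one global seed.
Per-stage seeds are derived deterministically from the global seed (spawn
indices of a ``numpy`` ``SeedSequence``), so identical configs reproduce every
output file byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import variant_io as vio
from .autoencoder import AutoencoderConfig, encode_individuals, train_autoencoder
from .cluster import (
    ClusterCensusRow,
    ClusterLabels,
    ReductionParams,
    cluster_gene_sets,
    coverage,
    grid_search,
    umap_project,
)
from .dbcv import dbcv_or_none
from .embedding import (
    build_phenotype_matrix,
    load_gene_embedding,
    read_genes_to_phenotype,
)
from .enrichment import (
    EnrichmentOptions,
    enrich_cluster,
    phenotype_fe,
    read_asd_gene_list,
    read_term_db,
    select_report,
    sfari_overlap,
)
from .synthetic import SyntheticConfig, write_inputs

__all__ = ["RunConfig", "RunReport", "derive_stage_seeds", "run_pipeline"]

_STAGE_NAMES = ("synthetic", "autoencoder", "umap_reduce", "umap_display")


def derive_stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) from one global seed."""
    state = np.random.SeedSequence(int(global_seed)).generate_state(len(_STAGE_NAMES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGE_NAMES, state)}


@dataclass
class RunConfig:
    """Everything needed for one pipeline run.

    Exactly one of ``synthetic`` or the five input paths must be provided.
    """

    outdir: str | Path
    seed: int
    synthetic: SyntheticConfig | None = None
    cohort_path: str | Path | None = None
    embedding_path: str | Path | None = None
    phenotype_path: str | Path | None = None
    term_db_path: str | Path | None = None
    asd_list_path: str | Path | None = None
    keep_sequencing: frozenset[vio.SequencingType] = frozenset(
        {vio.SequencingType.WHOLE_GENOME}
    )
    autoencoder_epochs: int = 200
    autoencoder_batch_size: int = 32
    autoencoder_latent_dim: int = 64
    autoencoder_layers: int = 6
    reduction: dict = field(
        default_factory=lambda: {"n_neighbors": 15, "n_components": 5, "metric": "cosine"}
    )
    grid_min_cluster_size: Sequence[int] = (25, 55, 105)
    grid_min_samples: Sequence[int] = (5, 10)
    grid_metric: Sequence[str] = ("euclidean", "manhattan")
    grid_selection_method: Sequence[str] = ("eom",)
    enrichment: EnrichmentOptions = field(default_factory=EnrichmentOptions)

    def validate(self) -> None:
        real_paths = [self.cohort_path, self.embedding_path, self.phenotype_path,
                      self.term_db_path, self.asd_list_path]
        if self.synthetic is not None:
            if any(p is not None for p in real_paths):
                raise ValueError("provide either synthetic config or real paths, not both")
        else:
            missing = [p for p in real_paths[:3] if p is None]
            if missing:
                raise ValueError("real-input run requires cohort, embedding and "
                                 "phenotype paths")
            for p in real_paths:
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
        if not self.keep_sequencing:
            raise ValueError("keep_sequencing must be non-empty")


@dataclass
class RunReport:
    """Per-stage record of one run: counts, parameters, seeds, manifest."""

    stages: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)  # filename -> sha256
    warnings: list[str] = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "manifest": self.manifest,
                "warnings": self.warnings, "timings": self.timings}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Output files: deduplicated events TSV, latent matrix TSV, cluster labels
    TSV, grid-search table TSV, 2-D display coordinates TSV, census TSV,
    per-cluster enrichment TSV, phenotype-FE TSV and ``report.json`` (stage
    records plus a sha256 manifest of every emitted file).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    seeds = derive_stage_seeds(cfg.seed)
    report.stages["seeds"] = dict(seeds)
    t0 = time.perf_counter()

    # --- inputs ------------------------------------------------------------
    if cfg.synthetic is not None:
        syn = SyntheticConfig(**{**cfg.synthetic.__dict__, "seed": cfg.synthetic.seed})
        input_paths = write_inputs(syn, outdir / "inputs")
        cohort_path = input_paths["cohort"]
        embedding_path = input_paths["embedding"]
        phenotype_path = input_paths["phenotypes"]
        term_db_path = input_paths["terms"]
        asd_list_path = input_paths["asd_list"]
        report.stages["synthetic"] = {"inputs": {k: str(v) for k, v in input_paths.items()}}
    else:
        cohort_path = Path(cfg.cohort_path)
        embedding_path = Path(cfg.embedding_path)
        phenotype_path = Path(cfg.phenotype_path)
        term_db_path = Path(cfg.term_db_path) if cfg.term_db_path else None
        asd_list_path = Path(cfg.asd_list_path) if cfg.asd_list_path else None

    # --- variant ingestion -------------------------------------------------
    ingest = vio.IngestionReport()
    events = vio.read_varicarta(cohort_path, report=ingest)
    events = vio.deduplicate_events(events, report=ingest)
    events = vio.filter_by_sequencing(events, cfg.keep_sequencing, report=ingest)
    gene_sets = vio.group_individuals(events, report=ingest)
    vio.write_events_tsv(events, outdir / "events_dedup_filtered.tsv")
    report.stages["variant_io"] = ingest.to_dict()
    report.timings["ingestion_s"] = round(time.perf_counter() - t0, 3)

    # --- embedding space ---------------------------------------------------
    t1 = time.perf_counter()
    emb = load_gene_embedding(embedding_path)
    annotations = read_genes_to_phenotype(phenotype_path)
    pheno_matrix = build_phenotype_matrix(annotations, emb)
    empty = [s.individual_id for s in gene_sets if not (set(s.genes) & set(emb.vocabulary))]
    ingest.empty_gene_set_individuals = empty
    if empty:
        report.warnings.append(
            f"{len(empty)} individual(s) have no in-vocabulary genes; retained"
        )
    report.stages["embedding_space"] = {
        "n_genes": emb.n_genes,
        "dim": emb.dim,
        "n_phenotypes": pheno_matrix.n_phenotypes,
        "flagged_phenotype_rows": int(pheno_matrix.flagged_rows.sum()),
        "stored_entries": int(pheno_matrix.matrix.nnz),
    }
    report.timings["embedding_s"] = round(time.perf_counter() - t1, 3)

    # --- latent encoder ----------------------------------------------------
    t2 = time.perf_counter()
    ae_cfg = AutoencoderConfig(
        input_dim=emb.n_genes,
        latent_dim=cfg.autoencoder_latent_dim,
        n_layers_each_side=cfg.autoencoder_layers,
        epochs=cfg.autoencoder_epochs,
        batch_size=cfg.autoencoder_batch_size,
        seed=seeds["autoencoder"],
    )
    model = train_autoencoder(pheno_matrix, ae_cfg)
    model.save(outdir / "encoder_model.npz")
    latent = encode_individuals(gene_sets, emb, model)
    _write_tsv(
        outdir / "latent.tsv",
        ["individual_id"] + [f"z{i}" for i in range(latent.values.shape[1])],
        [[iid] + [f"{v:.8g}" for v in row]
         for iid, row in zip(latent.individual_ids, latent.values)],
    )
    report.stages["latent_encoder"] = {
        "config": ae_cfg.to_dict(),
        "initial_loss": model.history[0],
        "final_loss": model.history[-1],
        "n_individuals": latent.n,
    }
    report.timings["autoencoder_s"] = round(time.perf_counter() - t2, 3)

    # --- clustering --------------------------------------------------------
    t3 = time.perf_counter()
    red = ReductionParams(seed=seeds["umap_reduce"], **cfg.reduction)
    points = umap_project(latent, red)
    labels, grid = grid_search(
        points,
        min_cluster_size=cfg.grid_min_cluster_size,
        min_samples=cfg.grid_min_samples,
        metric=cfg.grid_metric,
        cluster_selection_method=cfg.grid_selection_method,
    )
    best_dbcv = dbcv_or_none(points, labels.labels)
    cov = coverage(labels)
    display = umap_project(
        latent,
        ReductionParams(
            seed=seeds["umap_display"], n_neighbors=red.n_neighbors,
            n_components=2, metric=red.metric,
        ),
    )
    _write_tsv(
        outdir / "labels.tsv", ["individual_id", "cluster"],
        [[iid, int(c)] for iid, c in zip(latent.individual_ids, labels.labels)],
    )
    _write_tsv(
        outdir / "grid_search.tsv",
        ["min_cluster_size", "min_samples", "metric", "cluster_selection_method",
         "dbcv", "coverage", "n_clusters"],
        [[r.params.min_cluster_size, r.params.min_samples, r.params.metric,
          r.params.cluster_selection_method,
          "NA" if r.dbcv is None else f"{r.dbcv:.6f}",
          f"{r.coverage:.6f}", r.n_clusters] for r in grid],
    )
    _write_tsv(
        outdir / "coords_2d.tsv", ["individual_id", "x", "y", "cluster"],
        [[iid, f"{p[0]:.6f}", f"{p[1]:.6f}", int(c)]
         for iid, p, c in zip(latent.individual_ids, display, labels.labels)],
    )
    report.stages["cluster_engine"] = {
        "reduction": {"n_neighbors": red.n_neighbors, "n_components": red.n_components,
                      "metric": red.metric, "seed": red.seed},
        "n_clusters": labels.n_clusters,
        "coverage": cov,
        "dbcv": best_dbcv,
        "grid_cells": len(grid),
    }
    report.timings["clustering_s"] = round(time.perf_counter() - t3, 3)

    # --- census + enrichment -----------------------------------------------
    t4 = time.perf_counter()
    asd = read_asd_gene_list(asd_list_path) if asd_list_path else None
    census = cluster_gene_sets(labels, gene_sets, asd_genes=asd)
    _write_tsv(
        outdir / "census.tsv",
        ["cluster", "individuals", "genes", "asd_linked_genes"],
        [[r.cluster, r.n_members, r.n_genes,
          "" if r.n_asd_linked is None else r.n_asd_linked] for r in census],
    )
    enrichment_rows: list[list] = []
    pheno_rows: list[list] = []
    if term_db_path is not None:
        db = read_term_db(term_db_path, background=emb.vocabulary)
        for row in census:
            try:
                results = enrich_cluster(row.genes, db, cfg.enrichment)
            except ValueError as exc:
                report.warnings.append(f"cluster {row.cluster}: {exc}")
                continue
            reported = {r.term_id for r in select_report(results, cfg.enrichment)}
            for r in results:
                enrichment_rows.append(
                    [row.cluster, r.term_id, r.name, r.namespace, r.k, r.K, r.n,
                     r.N, f"{r.fold_enrichment:.6f}", f"{r.p_value:.6g}",
                     f"{r.fdr:.6g}", r.report_tier,
                     int(r.term_id in reported)]
                )
            fes = phenotype_fe(
                row.genes, annotations, frozenset(emb.vocabulary),
                fe_threshold=cfg.enrichment.phenotype_fe_threshold,
            )
            for fe in fes:
                pheno_rows.append(
                    [row.cluster, fe.phenotype_id, fe.name,
                     f"{fe.fold_enrichment:.6f}"]
                )
    _write_tsv(
        outdir / "enrichment.tsv",
        ["cluster", "term_id", "name", "namespace", "k", "K", "n", "N",
         "fold_enrichment", "p_value", "fdr", "report_tier", "reported"],
        enrichment_rows,
    )
    _write_tsv(
        outdir / "phenotype_fe.tsv",
        ["cluster", "phenotype_id", "name", "fold_enrichment"],
        pheno_rows,
    )
    report.stages["enrichment"] = {
        "n_clusters_enriched": len(census),
        "options": cfg.enrichment.__dict__,
        "asd_list_size": len(asd) if asd else None,
    }
    report.timings["enrichment_s"] = round(time.perf_counter() - t4, 3)

    # --- manifest ----------------------------------------------------------
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "report.json":
            report.manifest[str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
    )
    return report
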