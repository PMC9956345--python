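"""Synthetic inputs with planted structure for every pipeline stage.

The generator emulates the five input resources the pipeline consumes — a
gene embedding, phenotype->gene annotations, an ontology term database, a
variant-event cohort table, and an ASD-linked gene list — with known ground
truth so recovery can be scored:

* genes fall into M embedding-space modules (unit-norm centroids plus
  per-component Gaussian noise of spread sigma);
* each phenotype and each ontology term draws a fraction rho of its genes
  from its home module, the rest uniformly elsewhere;
* each cohort individual belongs to one of S latent subtypes and draws a
  fraction f of its variated genes from the subtype's module, the rest
  uniformly, written as whole-genome variant events with synthetic
  coordinates; duplicate rows (same event, different source paper) and
  out-of-vocabulary gene symbols are injected at configurable rates to
  exercise the ingestion edge paths.

All generators are pure functions of the config (seed included): regenerated
files are byte-identical.  Per-product randomness is derived from the seed
with fixed stream offsets so each artefact is stable under changes to the
others.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .embedding import GeneEmbedding, PhenotypeAnnotation
from .enrichment import NAMESPACES, TermAnnotationDB, TermRecord

__all__ = ["SyntheticConfig", "SyntheticCohort", "make_gene_embedding",
           "make_phenotype_annotations", "make_term_db", "make_variant_cohort",
           "make_asd_gene_list", "write_inputs"]

_STREAMS = {"embedding": 1, "phenotypes": 2, "terms": 3, "cohort": 4, "asd": 5}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the planted-structure generator."""

    seed: int
    n_genes: int = 300
    embed_dim: int = 50
    n_modules: int = 6
    module_spread: float = 0.05  # sigma: per-component noise around centroids
    n_phenotypes: int = 120
    genes_per_phenotype: int = 12
    phenotype_module_purity: float = 0.8  # rho
    n_subtypes: int = 3
    individuals_per_subtype: int = 60
    genes_per_individual: int = 40  # whole-genome catalogues average ~40 events/individual
    subtype_module_fraction: float = 0.9  # f
    n_terms: int = 42
    genes_per_term: int = 14
    term_module_purity: float = 0.8
    duplicate_rate: float = 0.05
    oov_rate: float = 0.02
    asd_list_fraction: float = 0.2
    max_centroid_cosine: float = 0.5

    def __post_init__(self) -> None:
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules must not exceed n_genes")
        if self.n_subtypes > self.n_modules:
            raise ValueError("n_subtypes must not exceed n_modules")
        for name in ("phenotype_module_purity", "subtype_module_fraction",
                     "term_module_purity", "duplicate_rate", "oov_rate",
                     "asd_list_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )


@dataclass
class SyntheticCohort:
    """Cohort table rows plus ground truth."""

    rows: list[dict]  # VariCarta-dialect rows, in written order
    truth_labels: dict[str, int]  # individual id -> subtype
    n_unique_events: int
    n_duplicate_rows: int


def _gene_names(cfg: SyntheticConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"SYNG{str(i + 1).zfill(width)}" for i in range(cfg.n_genes)]


def make_gene_embedding(
    cfg: SyntheticConfig,
) -> tuple[GeneEmbedding, np.ndarray, dict]:
    """Gene embedding with M planted modules.

    Returns ``(embedding, module_of_gene, info)`` where ``info`` reports the
    maximum pairwise cosine similarity among centroids (kept below
    ``cfg.max_centroid_cosine`` by rejection sampling).
    """
    rng = cfg.rng("embedding")
    for _ in range(200):
        centroids = rng.normal(size=(cfg.n_modules, cfg.embed_dim))
        centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
        sims = centroids @ centroids.T
        np.fill_diagonal(sims, 0.0)
        max_sim = float(np.abs(sims).max()) if cfg.n_modules > 1 else 0.0
        if max_sim < cfg.max_centroid_cosine:
            break
    else:
        raise RuntimeError(
            f"could not draw {cfg.n_modules} centroids with pairwise cosine "
            f"below {cfg.max_centroid_cosine} in {cfg.embed_dim} dims"
        )
    modules = np.arange(cfg.n_genes) % cfg.n_modules
    vectors = centroids[modules] + rng.normal(
        0.0, cfg.module_spread, size=(cfg.n_genes, cfg.embed_dim)
    )
    emb = GeneEmbedding(vocabulary=_gene_names(cfg), vectors=vectors)
    return emb, modules, {"max_centroid_cosine": max_sim}


def _module_biased_draw(
    rng: np.random.Generator,
    modules: np.ndarray,
    home_module: int,
    size: int,
    purity: float,
) -> np.ndarray:
    """Draw ``size`` distinct gene indices, a fraction ``purity`` from the
    home module and the rest uniformly from the other genes."""
    home = np.flatnonzero(modules == home_module)
    away = np.flatnonzero(modules != home_module)
    n_home = min(int(round(purity * size)), home.size)
    n_away = min(size - n_home, away.size)
    picked = [rng.choice(home, size=n_home, replace=False)]
    if n_away:
        picked.append(rng.choice(away, size=n_away, replace=False))
    return np.sort(np.concatenate(picked))


def make_phenotype_annotations(
    cfg: SyntheticConfig, modules: np.ndarray
) -> tuple[list[PhenotypeAnnotation], np.ndarray]:
    """Phenotype annotations, each tied to a home module (returned as truth)."""
    rng = cfg.rng("phenotypes")
    names = _gene_names(cfg)
    home = np.arange(cfg.n_phenotypes) % cfg.n_modules
    anns = []
    for p in range(cfg.n_phenotypes):
        idx = _module_biased_draw(
            rng, modules, int(home[p]), cfg.genes_per_phenotype,
            cfg.phenotype_module_purity,
        )
        anns.append(
            PhenotypeAnnotation(
                phenotype_id=f"HP:{p + 1:07d}",
                name=f"Synthetic phenotype {p + 1}",
                genes=frozenset(names[i] for i in idx),
            )
        )
    return anns, home


def make_term_db(
    cfg: SyntheticConfig, modules: np.ndarray
) -> tuple[TermAnnotationDB, np.ndarray]:
    """Ontology-style term database, terms cycling through the namespaces."""
    rng = cfg.rng("terms")
    names = _gene_names(cfg)
    home = np.arange(cfg.n_terms) % cfg.n_modules
    terms = {}
    for tnum in range(cfg.n_terms):
        idx = _module_biased_draw(
            rng, modules, int(home[tnum]), cfg.genes_per_term, cfg.term_module_purity
        )
        tid = f"GO:{tnum + 1:07d}"
        terms[tid] = TermRecord(
            term_id=tid,
            name=f"Synthetic term {tnum + 1}",
            namespace=NAMESPACES[tnum % len(NAMESPACES)],
            genes=frozenset(names[i] for i in idx),
        )
    db = TermAnnotationDB(terms=terms, background=frozenset(names))
    return db, home


def make_variant_cohort(
    cfg: SyntheticConfig, modules: np.ndarray
) -> SyntheticCohort:
    """Cohort of S*individuals_per_subtype individuals as variant-event rows.

    Subtype s (home module s) draws a fraction f of each individual's genes
    from module s.  Every unique event is one row; a ``duplicate_rate``
    fraction of events is re-emitted with a different source-paper id
    (exercising deduplication), and an ``oov_rate`` fraction of individuals
    receives one extra event on a gene absent from the embedding vocabulary.
    """
    rng = cfg.rng("cohort")
    names = _gene_names(cfg)
    rows: list[dict] = []
    truth: dict[str, int] = {}
    n_ind = cfg.n_subtypes * cfg.individuals_per_subtype
    width = len(str(n_ind))
    n_unique = 0
    duplicates: list[dict] = []
    for i in range(n_ind):
        subtype = i % cfg.n_subtypes
        ind = f"IND{str(i + 1).zfill(width)}"
        truth[ind] = subtype
        idx = _module_biased_draw(
            rng, modules, subtype, cfg.genes_per_individual,
            cfg.subtype_module_fraction,
        )
        symbols = [names[j] for j in idx]
        if rng.random() < cfg.oov_rate:
            symbols.append(f"NOVEL{i + 1}")
        for sym in symbols:
            pos = int(rng.integers(1, 10_000_000))
            row = {
                "individual_id": ind,
                "gene_symbol": sym,
                "sequencing_type": "whole genome sequencing",
                "variant_category": "nonsynonymous SNV",
                "chromosome": f"chr{1 + int(idx[0]) % 22}",
                "position": str(pos),
                "ref": "A",
                "alt": "G",
                "source": "SYNTH-2023-A",
            }
            rows.append(row)
            n_unique += 1
            if rng.random() < cfg.duplicate_rate:
                dup = dict(row)
                dup["source"] = "SYNTH-2023-B"
                duplicates.append(dup)
    rows.extend(duplicates)
    return SyntheticCohort(
        rows=rows, truth_labels=truth,
        n_unique_events=n_unique, n_duplicate_rows=len(duplicates),
    )


def make_asd_gene_list(cfg: SyntheticConfig) -> frozenset[str]:
    """A curated-list stand-in: a random fraction of the vocabulary."""
    rng = cfg.rng("asd")
    names = _gene_names(cfg)
    n = int(round(cfg.asd_list_fraction * cfg.n_genes))
    idx = rng.choice(cfg.n_genes, size=n, replace=False)
    return frozenset(names[i] for i in sorted(idx))


def write_inputs(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every input dialect the pipeline reads, plus a truth JSON.

    Emits Gene2Vec text, genes_to_phenotype TSV, term-db TSV, cohort CSV,
    ASD-list text and ``truth.json``; returns the path of each artefact.
    Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emb, modules, info = make_gene_embedding(cfg)
    anns, pheno_home = make_phenotype_annotations(cfg, modules)
    db, term_home = make_term_db(cfg, modules)
    cohort = make_variant_cohort(cfg, modules)
    asd = make_asd_gene_list(cfg)

    paths = {name: outdir / fname for name, fname in [
        ("embedding", "gene_embedding.txt"),
        ("phenotypes", "genes_to_phenotype.tsv"),
        ("terms", "term_db.tsv"),
        ("cohort", "cohort.csv"),
        ("asd_list", "asd_genes.txt"),
        ("truth", "truth.json"),
    ]}

    with paths["embedding"].open("w", encoding="utf-8") as fh:
        for sym, vec in zip(emb.vocabulary, emb.vectors):
            fh.write(sym + " " + " ".join(f"{v:.8f}" for v in vec) + "\n")

    with paths["phenotypes"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_symbol", "hpo_id", "hpo_name"])
        for ann in anns:
            for sym in sorted(ann.genes):
                w.writerow([sym, ann.phenotype_id, ann.name])

    with paths["terms"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term_id", "namespace", "name", "gene_symbol"])
        for tid in sorted(db.terms):
            rec = db.terms[tid]
            for sym in sorted(rec.genes):
                w.writerow([tid, rec.namespace, rec.name, sym])

    with paths["cohort"].open("w", newline="", encoding="utf-8") as fh:
        fieldnames = ["individual_id", "gene_symbol", "sequencing_type",
                      "variant_category", "chromosome", "position", "ref",
                      "alt", "source"]
        w = csv.DictWriter(fh, fieldnames=fieldnames, lineterminator="\n")
        w.writeheader()
        w.writerows(cohort.rows)

    paths["asd_list"].write_text("\n".join(sorted(asd)) + "\n", encoding="utf-8")

    truth = {
        "config": asdict(cfg),
        "module_of_gene": {g: int(m) for g, m in zip(emb.vocabulary, modules)},
        "phenotype_home_module": {a.phenotype_id: int(m) for a, m in zip(anns, pheno_home)},
        "term_home_module": {tid: int(m) for tid, m in zip(sorted(db.terms), term_home)},
        "subtype_of_individual": cohort.truth_labels,
        "n_unique_events": cohort.n_unique_events,
        "n_duplicate_rows": cohort.n_duplicate_rows,
        "max_centroid_cosine": info["max_centroid_cosine"],
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8")
    return paths
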