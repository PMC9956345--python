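"""Over-representation analysis of cluster gene sets.

Each cluster's gene set is compared with every term of an annotation database
(GO-style biological_process / cellular_component / molecular_function terms)
via a 2x2 Fisher exact test against a background gene universe, adjusted per
cluster with Benjamini-Hochberg, and effect sizes are reported as fold
enrichment FE = k / (n*K/N), the observed over expected overlap for

    k = cluster genes annotated to the term,
    n = cluster genes in the background,
    K = term genes in the background,
    N = background size.

Reporting follows fixed rules: the primary report keeps terms with
FDR < 0.005 and FE >= 1.5 ranked by FE descending; when that set is empty but
significant terms exist, the fallback report shows the top 20 by FDR; an
empty report is a legitimate outcome.  Phenotype fold enrichment applies the
same FE formula with each phenotype's gene set as the term (FE only, no
p-value), reporting FE > 1.0 ranked by FE.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .embedding import PhenotypeAnnotation

__all__ = [
    "NAMESPACES",
    "TermRecord",
    "TermAnnotationDB",
    "EnrichmentResult",
    "PhenotypeFE",
    "EnrichmentOptions",
    "fold_enrichment",
    "fisher_p",
    "bh_fdr",
    "enrich_cluster",
    "select_report",
    "phenotype_fe",
    "sfari_overlap",
    "read_term_db",
    "read_asd_gene_list",
]

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass(frozen=True)
class TermRecord:
    term_id: str
    name: str
    namespace: str
    genes: frozenset[str]


@dataclass
class TermAnnotationDB:
    """Term -> gene-set annotations over a background gene universe.

    Term gene sets are clipped to the background at construction so the
    invariant ``genes(term) <= background`` always holds.
    """

    terms: dict[str, TermRecord]
    background: frozenset[str]

    def __post_init__(self) -> None:
        clipped = {}
        for tid, rec in self.terms.items():
            genes = rec.genes & self.background
            clipped[tid] = TermRecord(rec.term_id, rec.name, rec.namespace, genes)
        self.terms = clipped

    @property
    def n_background(self) -> int:
        return len(self.background)

    def restricted_to(self, universe: Iterable[str]) -> "TermAnnotationDB":
        """New DB with the background intersected with ``universe``."""
        return TermAnnotationDB(
            terms=dict(self.terms), background=self.background & frozenset(universe)
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of one cluster gene set with one term."""

    term_id: str
    name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_value: float
    fdr: float
    report_tier: str = ""  # "primary" | "fallback" | ""


@dataclass(frozen=True)
class PhenotypeFE:
    phenotype_id: str
    name: str
    fold_enrichment: float


@dataclass
class EnrichmentOptions:
    """Thresholds of the reporting rules (defaults as used in the analysis)."""

    fdr_threshold: float = 0.005
    fe_threshold: float = 1.5
    fallback_top: int = 20
    min_term_size: int = 0  # 0 = no minimum
    phenotype_fe_threshold: float = 1.0


class UndefinedTermError(ValueError):
    """FE undefined: the term or the cluster has no background genes."""


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed over expected overlap, ``k / (n*K/N)``; 0 when k = 0."""
    if n < 1 or K < 1:
        raise UndefinedTermError(f"fold enrichment undefined for n={n}, K={K}")
    if N < max(n, K):
        raise ValueError(f"inconsistent counts: N={N} < max(n={n}, K={K})")
    if k == 0:
        return 0.0
    return k / (n * K / N)


def fisher_p(k: int, n: int, K: int, N: int) -> float:
    """Two-tailed Fisher exact p for the table [[k, n-k], [K-k, N-n-K+k]].

    Two-sided in the standard sense: the sum of hypergeometric outcomes whose
    probability does not exceed that of the observed table.
    """
    cells = (k, n - k, K - k, N - n - K + k)
    if any(c < 0 for c in cells):
        raise ValueError(f"inconsistent 2x2 counts k={k}, n={n}, K={K}, N={N}")
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    return float(fisher_exact(table, alternative="two-sided").pvalue)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_cluster(
    cluster_genes: Iterable[str],
    db: TermAnnotationDB,
    opts: EnrichmentOptions | None = None,
) -> list[EnrichmentResult]:
    """Test one cluster gene set against every term of the database.

    All namespaces form a single BH family per cluster.  Terms with no
    background genes (or below ``min_term_size``) are skipped.  Results are
    returned for every tested term, sorted by FDR then term id, with
    ``report_tier`` already assigned (see :func:`select_report`).
    """
    opts = opts or EnrichmentOptions()
    cluster = frozenset(g.strip().upper() for g in cluster_genes)
    in_bg = cluster & db.background
    n = len(in_bg)
    if n == 0:
        raise ValueError(
            f"cluster gene set ({len(cluster)} genes) has no overlap with the "
            "background universe"
        )
    N = db.n_background

    tested: list[tuple[TermRecord, int, int, float, float]] = []
    for tid in sorted(db.terms):
        rec = db.terms[tid]
        K = len(rec.genes)
        if K < max(1, opts.min_term_size):
            continue
        k = len(in_bg & rec.genes)
        fe = fold_enrichment(k, n, K, N)
        p = fisher_p(k, n, K, N)
        tested.append((rec, k, K, fe, p))
    if not tested:
        return []

    fdrs = bh_fdr([t[4] for t in tested])
    results = [
        EnrichmentResult(
            term_id=rec.term_id, name=rec.name, namespace=rec.namespace,
            k=k, n=n, K=K, N=N, fold_enrichment=fe, p_value=p, fdr=float(q),
        )
        for (rec, k, K, fe, p), q in zip(tested, fdrs)
    ]
    return _assign_tiers(results, opts)


def _assign_tiers(
    results: list[EnrichmentResult], opts: EnrichmentOptions
) -> list[EnrichmentResult]:
    significant = [r for r in results if r.fdr < opts.fdr_threshold]
    primary = {
        r.term_id for r in significant if r.fold_enrichment >= opts.fe_threshold
    }
    fallback: set[str] = set()
    if not primary and significant:
        ranked = sorted(significant, key=lambda r: (r.fdr, r.term_id))
        fallback = {r.term_id for r in ranked[: opts.fallback_top]}
    out = []
    for r in results:
        tier = "primary" if r.term_id in primary else (
            "fallback" if r.term_id in fallback else ""
        )
        out.append(
            EnrichmentResult(**{**r.__dict__, "report_tier": tier})
        )
    return sorted(out, key=lambda r: (r.fdr, r.term_id))


def select_report(
    results: Sequence[EnrichmentResult], opts: EnrichmentOptions | None = None
) -> list[EnrichmentResult]:
    """The ranked report rows for one cluster.

    Primary tier (FDR < threshold and FE >= threshold) ranked by FE
    descending; otherwise the fallback tier (top ``fallback_top`` significant
    terms) ranked by FDR ascending; otherwise empty.
    """
    primary = [r for r in results if r.report_tier == "primary"]
    if primary:
        return sorted(primary, key=lambda r: (-r.fold_enrichment, r.term_id))
    fallback = [r for r in results if r.report_tier == "fallback"]
    return sorted(fallback, key=lambda r: (r.fdr, r.term_id))


def phenotype_fe(
    cluster_genes: Iterable[str],
    phenotypes: Sequence[PhenotypeAnnotation],
    background: frozenset[str] | set[str],
    *,
    fe_threshold: float = 1.0,
) -> list[PhenotypeFE]:
    """Fold enrichment of the cluster against each phenotype's gene set.

    Same FE formula with the phenotype's in-background gene set as the term;
    no p-value is attached.  Phenotypes with empty in-background gene sets
    are skipped; the report keeps FE > ``fe_threshold`` ranked by FE.
    """
    background = frozenset(background)
    cluster = frozenset(g.strip().upper() for g in cluster_genes)
    in_bg = cluster & background
    n = len(in_bg)
    if n == 0:
        raise ValueError("cluster gene set has no overlap with the background")
    N = len(background)
    out: list[PhenotypeFE] = []
    for ann in phenotypes:
        term = ann.genes & background
        K = len(term)
        if K == 0:
            continue
        fe = fold_enrichment(len(in_bg & term), n, K, N)
        if fe > fe_threshold:
            out.append(PhenotypeFE(ann.phenotype_id, ann.name, fe))
    return sorted(out, key=lambda r: (-r.fold_enrichment, r.phenotype_id))


def sfari_overlap(
    cluster_genes: Iterable[str], asd_list: Iterable[str]
) -> tuple[int, list[str]]:
    """Count and list the cluster genes present in a curated ASD gene list."""
    overlap = sorted(
        frozenset(g.strip().upper() for g in cluster_genes)
        & frozenset(g.strip().upper() for g in asd_list)
    )
    return len(overlap), overlap


def read_term_db(
    path: str | Path,
    *,
    background: Iterable[str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> TermAnnotationDB:
    """Read a term->gene TSV (term_id, namespace, name, gene_symbol per row).

    When ``background`` is None the universe defaults to all annotated genes.
    """
    cmap = {
        "term_id": "term_id", "namespace": "namespace",
        "name": "name", "gene_symbol": "gene_symbol",
    }
    if column_map:
        cmap.update(column_map)
    names: dict[str, str] = {}
    spaces: dict[str, str] = {}
    genes: dict[str, set[str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            tid = (row.get(cmap["term_id"]) or "").strip()
            sym = (row.get(cmap["gene_symbol"]) or "").strip().upper()
            if not tid or not sym:
                continue
            genes.setdefault(tid, set()).add(sym)
            names.setdefault(tid, (row.get(cmap["name"]) or "").strip())
            spaces.setdefault(tid, (row.get(cmap["namespace"]) or "").strip())
    terms = {
        tid: TermRecord(tid, names[tid], spaces[tid], frozenset(genes[tid]))
        for tid in genes
    }
    if background is None:
        bg: frozenset[str] = frozenset().union(*genes.values()) if genes else frozenset()
    else:
        bg = frozenset(g.strip().upper() for g in background)
    return TermAnnotationDB(terms=terms, background=bg)


def read_asd_gene_list(path: str | Path, *, symbol_column: str = "gene-symbol") -> frozenset[str]:
    """Read an ASD-linked gene list: one symbol per line, or a CSV with a
    symbol column (SFARI-style)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        fh.seek(0)
        if "," in first:
            reader = csv.DictReader(fh)
            if reader.fieldnames and symbol_column in reader.fieldnames:
                return frozenset(
                    (row[symbol_column] or "").strip().upper()
                    for row in reader
                    if (row[symbol_column] or "").strip()
                )
            fh.seek(0)
        return frozenset(
            line.strip().upper() for line in fh if line.strip()
        )
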