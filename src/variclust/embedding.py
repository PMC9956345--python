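"""Gene embedding space and max-of-components vector construction.

A pretrained gene embedding (Gene2Vec text format: one gene symbol followed by
D whitespace-separated floats per line) defines the column space of every
vector the pipeline builds.  Each gene is collapsed to a scalar — the maximum
of its D embedding components — and both phenotype vectors (from HPO
phenotype->gene annotations) and per-individual vectors place that scalar at
the gene's fixed column, leaving every unannotated column at zero.  The result
is a very sparse phenotype x gene matrix and, per individual, a G-dimensional
vector in the same column space.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GeneEmbedding",
    "PhenotypeAnnotation",
    "PhenotypeMatrix",
    "OutOfVocabularyError",
    "load_gene_embedding",
    "read_genes_to_phenotype",
    "gene_scalar",
    "build_phenotype_matrix",
    "build_individual_vector",
    "build_individual_matrix",
    "export_phenotype_matrix",
]


class OutOfVocabularyError(KeyError):
    """A gene symbol is absent from the embedding vocabulary."""


@dataclass
class GeneEmbedding:
    """Gene symbol -> D-dimensional real vector, with a fixed column order."""

    vocabulary: list[str]
    vectors: np.ndarray  # shape (G, D)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError("vocabulary length does not match vector rows")
        self._index = {g: i for i, g in enumerate(self.vocabulary)}
        if len(self._index) != len(self.vocabulary):
            raise ValueError("vocabulary contains duplicate symbols")

    @property
    def n_genes(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise OutOfVocabularyError(gene) from None

    def vector(self, gene: str) -> np.ndarray:
        return self.vectors[self.index_of(gene)]


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """One phenotype term with its annotated gene set."""

    phenotype_id: str
    name: str
    genes: frozenset[str]


@dataclass
class PhenotypeMatrix:
    """Sparse P x G matrix of per-gene scalars, columns = embedding vocabulary.

    An entry is *stored* at (p, g) exactly when gene g is in-vocabulary and
    annotated to phenotype p — even when the stored scalar happens to be 0.0 —
    so the sparsity pattern is the annotation structure itself.
    """

    phenotype_ids: list[str]
    phenotype_names: list[str]
    matrix: sp.csr_matrix  # P x G
    row_gene_counts: np.ndarray  # in-vocabulary annotated genes per row
    flagged_rows: np.ndarray  # boolean mask: no in-vocabulary genes

    @property
    def n_phenotypes(self) -> int:
        return self.matrix.shape[0]

    def dense_rows(self, include_flagged: bool = False) -> np.ndarray:
        """Dense row matrix, by default restricted to non-flagged rows."""
        if include_flagged:
            return np.asarray(self.matrix.todense())
        return np.asarray(self.matrix[~self.flagged_rows].todense())


def load_gene_embedding(path: str | Path) -> GeneEmbedding:
    """Load a Gene2Vec-format text embedding.

    Every line must carry the same number of float components; duplicate
    symbols, ragged lines and non-numeric tokens are fatal with the offending
    line number or symbol named.
    """
    path = Path(path)
    symbols: list[str] = []
    seen: set[str] = set()
    rows: list[np.ndarray] = []
    dim: int | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            symbol = parts[0].strip().upper()
            try:
                values = np.array([float(tok) for tok in parts[1:]], dtype=np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric component ({exc})") from None
            if values.size == 0:
                raise ValueError(f"{path}:{lineno}: no components for symbol {symbol!r}")
            if dim is None:
                dim = values.size
            elif values.size != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} components, got {values.size}"
                )
            if symbol in seen:
                raise ValueError(f"{path}: duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            symbols.append(symbol)
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty embedding file")
    return GeneEmbedding(vocabulary=symbols, vectors=np.vstack(rows))


def read_genes_to_phenotype(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> list[PhenotypeAnnotation]:
    """Read an HPO ``genes_to_phenotype``-dialect TSV into annotations.

    One row per (gene, phenotype) pair; rows are aggregated per phenotype id
    in first-appearance order.  Default columns: ``gene_symbol``, ``hpo_id``,
    ``hpo_name``.
    """
    cmap = {"gene_symbol": "gene_symbol", "hpo_id": "hpo_id", "hpo_name": "hpo_name"}
    if column_map:
        cmap.update(column_map)
    order: list[str] = []
    names: dict[str, str] = {}
    genes: dict[str, set[str]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for logical, col in cmap.items():
            if logical != "hpo_name" and (reader.fieldnames is None or col not in reader.fieldnames):
                raise ValueError(f"required column {col!r} missing from {path}")
        for row in reader:
            pid = (row.get(cmap["hpo_id"]) or "").strip()
            sym = (row.get(cmap["gene_symbol"]) or "").strip().upper()
            if not pid or not sym:
                continue
            if pid not in genes:
                order.append(pid)
                genes[pid] = set()
                names[pid] = (row.get(cmap["hpo_name"]) or "").strip()
            genes[pid].add(sym)
    return [
        PhenotypeAnnotation(phenotype_id=pid, name=names[pid], genes=frozenset(genes[pid]))
        for pid in order
    ]


def gene_scalar(gene: str, emb: GeneEmbedding) -> float:
    """Maximum of the gene's D embedding components (may be negative)."""
    return float(emb.vector(gene).max())


def build_phenotype_matrix(
    annotations: Sequence[PhenotypeAnnotation], emb: GeneEmbedding
) -> PhenotypeMatrix:
    """Assemble the sparse phenotype x gene matrix by the max-of-components rule.

    Rows follow annotation order; out-of-vocabulary genes are dropped and rows
    left without any in-vocabulary gene are flagged (retained in the matrix,
    excluded from autoencoder training by default).
    """
    scalars = emb.vectors.max(axis=1)
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    counts = np.zeros(len(annotations), dtype=np.int64)
    for p, ann in enumerate(annotations):
        for g in sorted(ann.genes):
            if g in emb:
                j = emb.index_of(g)
                rows.append(p)
                cols.append(j)
                data.append(scalars[j])
                counts[p] += 1
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(annotations), emb.n_genes), dtype=np.float64
    )
    return PhenotypeMatrix(
        phenotype_ids=[a.phenotype_id for a in annotations],
        phenotype_names=[a.name for a in annotations],
        matrix=mat,
        row_gene_counts=counts,
        flagged_rows=counts == 0,
    )


def export_phenotype_matrix(
    pm: PhenotypeMatrix, emb: GeneEmbedding, prefix: str | Path
) -> None:
    """Write the matrix as MatrixMarket plus row/column label files.

    Emits ``<prefix>.mtx``, ``<prefix>.rows.txt`` (phenotype ids) and
    ``<prefix>.cols.txt`` (the embedding vocabulary, in column order).
    """
    import scipy.io as sio

    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), pm.matrix.tocoo())
    prefix.with_suffix(".rows.txt").write_text(
        "\n".join(pm.phenotype_ids) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(".cols.txt").write_text(
        "\n".join(emb.vocabulary) + "\n", encoding="utf-8"
    )


def build_individual_vector(
    genes: frozenset[str] | set[str], emb: GeneEmbedding
) -> tuple[np.ndarray, int]:
    """G-dimensional vector for one individual's gene set.

    Component g equals the gene's max-of-components scalar when g is in the
    set and in-vocabulary, zero otherwise.  Returns ``(vector, n_dropped)``
    where ``n_dropped`` counts out-of-vocabulary genes.
    """
    vec = np.zeros(emb.n_genes, dtype=np.float64)
    dropped = 0
    for g in genes:
        if g in emb:
            j = emb.index_of(g)
            vec[j] = emb.vectors[j].max()
        else:
            dropped += 1
    return vec, dropped


def build_individual_matrix(
    gene_sets: Sequence[frozenset[str] | set[str]], emb: GeneEmbedding
) -> tuple[np.ndarray, np.ndarray]:
    """Stack individual vectors into an n x G matrix; per-row dropped counts."""
    n = len(gene_sets)
    mat = np.zeros((n, emb.n_genes), dtype=np.float64)
    dropped = np.zeros(n, dtype=np.int64)
    for i, genes in enumerate(gene_sets):
        mat[i], dropped[i] = build_individual_vector(genes, emb)
    return mat, dropped
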