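"""UMAP reduction, HDBSCAN clustering, DBCV-scored grid search, census.

The latent matrix (individuals x 64) is projected to a low-dimensional space
with UMAP (defaults: 15 neighbours, 5 components, cosine metric), clustered
with HDBSCAN under an exhaustive hyperparameter grid, and each grid cell is
scored by the DBCV validity index plus coverage (the fraction of samples not
labelled noise).  The winning labelling's per-cluster gene sets feed the
enrichment stage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autoencoder import LatentMatrix
from .dbcv import dbcv_or_none
from .variant_io import IndividualGeneSet

__all__ = [
    "ReductionParams",
    "ClusterParams",
    "ClusterLabels",
    "GridSearchResult",
    "ClusterCensusRow",
    "umap_project",
    "hdbscan_cluster",
    "coverage",
    "grid_search",
    "cluster_gene_sets",
]

NOISE = -1


@dataclass(frozen=True)
class ReductionParams:
    """UMAP hyperparameters for the 64 -> n_components projection."""

    seed: int
    n_neighbors: int = 15
    n_components: int = 5
    metric: str = "cosine"

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")


@dataclass(frozen=True)
class ClusterParams:
    """HDBSCAN hyperparameters explored by the grid search."""

    min_cluster_size: int
    min_samples: int
    metric: str = "euclidean"  # euclidean | manhattan
    cluster_selection_method: str = "eom"  # eom | leaf

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class ClusterLabels:
    """Integer label per individual; -1 marks noise."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    @property
    def n(self) -> int:
        return int(self.labels.shape[0])


@dataclass
class GridSearchResult:
    """Score record for one grid combination."""

    params: ClusterParams
    dbcv: float | None  # None = undefined (degenerate clustering)
    coverage: float
    n_clusters: int


@dataclass
class ClusterCensusRow:
    """Per-cluster membership summary (census)."""

    cluster: int
    n_members: int
    genes: frozenset[str]
    n_genes: int
    n_asd_linked: int | None = None
    asd_linked: frozenset[str] | None = None


def umap_project(latent: LatentMatrix | np.ndarray, p: ReductionParams) -> np.ndarray:
    """Project latent rows to ``p.n_components`` dimensions with UMAP.

    Deterministic for a fixed seed (``random_state`` forces single-threaded
    layout optimisation).  Requires more samples than neighbours.
    """
    import umap  # deferred: numba JIT on import is expensive

    x = latent.values if isinstance(latent, LatentMatrix) else np.asarray(latent)
    if x.shape[0] <= p.n_neighbors:
        raise ValueError(
            f"n={x.shape[0]} samples <= n_neighbors={p.n_neighbors}; "
            "lower n_neighbors"
        )
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; intended
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_neighbors=p.n_neighbors,
            n_components=p.n_components,
            metric=p.metric,
            random_state=p.seed,
        )
        return np.asarray(reducer.fit_transform(x), dtype=np.float64)


def hdbscan_cluster(points: np.ndarray, p: ClusterParams) -> ClusterLabels:
    """Run HDBSCAN; fewer samples than ``min_cluster_size`` yields all noise."""
    from sklearn.cluster import HDBSCAN

    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if n < p.min_cluster_size:
        warnings.warn(
            f"n={n} < min_cluster_size={p.min_cluster_size}: all points noise",
            stacklevel=2,
        )
        return ClusterLabels(labels=np.full(n, NOISE))
    model = HDBSCAN(
        min_cluster_size=p.min_cluster_size,
        min_samples=p.min_samples,
        metric=p.metric,
        cluster_selection_method=p.cluster_selection_method,
        copy=True,
    )
    return ClusterLabels(labels=model.fit_predict(points))


def coverage(labels: ClusterLabels) -> float:
    """Fraction of samples assigned to any cluster (1 - noise fraction)."""
    if labels.n == 0:
        raise ValueError("coverage undefined for zero samples")
    return float(np.count_nonzero(labels.labels != NOISE) / labels.n)


def grid_search(
    points: np.ndarray,
    *,
    min_cluster_size: Sequence[int],
    min_samples: Sequence[int],
    metric: Sequence[str] = ("euclidean", "manhattan"),
    cluster_selection_method: Sequence[str] = ("eom",),
) -> tuple[ClusterLabels, list[GridSearchResult]]:
    """Exhaustively evaluate the HDBSCAN grid, scored by DBCV.

    Every combination is clustered and scored; the winner maximises DBCV,
    with ties broken by higher coverage, then larger ``min_cluster_size``,
    then grid order.  An undefined DBCV (fewer than two clusters of size two)
    ranks below every defined score.  DBCV is always computed with Euclidean
    distances in ``points``' space so scores are comparable across metrics.
    """
    combos = list(
        itertools.product(min_cluster_size, min_samples, metric, cluster_selection_method)
    )
    if not combos:
        raise ValueError("grid is empty")
    results: list[GridSearchResult] = []
    labellings: list[ClusterLabels] = []
    for mcs, ms, met, sel in combos:
        params = ClusterParams(
            min_cluster_size=mcs, min_samples=ms, metric=met,
            cluster_selection_method=sel,
        )
        labels = hdbscan_cluster(points, params)
        score = dbcv_or_none(points, labels.labels)
        results.append(
            GridSearchResult(
                params=params, dbcv=score, coverage=coverage(labels),
                n_clusters=labels.n_clusters,
            )
        )
        labellings.append(labels)
    if all(r.dbcv is None for r in results):
        raise RuntimeError(
            "all grid combinations produced degenerate clusterings; "
            f"grid table: {results!r}"
        )
    best = max(
        range(len(results)),
        key=lambda i: (
            results[i].dbcv if results[i].dbcv is not None else -np.inf,
            results[i].coverage,
            results[i].params.min_cluster_size,
            -i,
        ),
    )
    return labellings[best], results


def cluster_gene_sets(
    labels: ClusterLabels,
    sets: Sequence[IndividualGeneSet],
    *,
    asd_genes: frozenset[str] | set[str] | None = None,
) -> list[ClusterCensusRow]:
    """Union of member gene sets per cluster, noise excluded.

    When ``asd_genes`` is given, each row also carries the intersection of the
    cluster's genes with that curated ASD-linked list.
    """
    if labels.n != len(sets):
        raise ValueError(
            f"labels ({labels.n}) and gene sets ({len(sets)}) are misaligned"
        )
    rows: list[ClusterCensusRow] = []
    for c in sorted(set(labels.labels[labels.labels != NOISE])):
        idx = np.flatnonzero(labels.labels == c)
        genes: set[str] = set()
        for i in idx:
            genes |= sets[i].genes
        overlap = frozenset(genes & set(asd_genes)) if asd_genes is not None else None
        rows.append(
            ClusterCensusRow(
                cluster=int(c),
                n_members=int(idx.size),
                genes=frozenset(genes),
                n_genes=len(genes),
                n_asd_linked=len(overlap) if overlap is not None else None,
                asd_linked=overlap,
            )
        )
    return rows
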