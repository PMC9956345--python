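"""Density-based clustering validation (DBCV) index.

DBCV scores a flat clustering with noise in [-1, 1] by comparing, for every
cluster, its internal density sparseness against its density separation from
the other clusters, using all-points core distances and mutual-reachability
minimum spanning trees:

* the all-points core distance of a point x in a cluster of size n_c is the
  inverse generalized mean of inverse distances,
  ``( sum_{y != x} (1/d(x,y))^dim / (n_c - 1) )^(-1/dim)``;
* the mutual reachability distance of x, y is
  ``max(coredist(x), coredist(y), d(x,y))``;
* the density sparseness of a cluster (DSC) is the largest *internal* edge of
  the MST built on its mutual-reachability graph (an edge is internal when
  both endpoints have MST degree > 1; for clusters too small to have internal
  edges the maximum MST edge is used);
* the density separation of two clusters (DSPC) is the minimum mutual
  reachability distance between their internal nodes (falling back to all
  nodes for tiny clusters);
* each cluster scores ``(min_j DSPC - DSC) / max(min_j DSPC, DSC)`` and the
  index is the size-weighted sum over clusters, where the weights divide by
  the *total* sample count so noise points dilute the score.

Clusters need at least two members to have a defined core distance; with
fewer than two such clusters the index is undefined and
:class:`UndefinedDBCVError` is raised (grid search ranks it below every
defined score).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["UndefinedDBCVError", "dbcv", "dbcv_or_none"]

NOISE = -1


class UndefinedDBCVError(ValueError):
    """The clustering has fewer than two clusters of size >= 2."""


def _all_points_core_distances(dist: np.ndarray, dim: int) -> np.ndarray:
    """All-points core distance for every member of one cluster.

    ``dist`` is the cluster's internal distance matrix.  Coincident points
    (zero distance) drive the inverse-distance mean to infinity and hence the
    core distance to zero.
    """
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 1.0 / np.where(dist > 0, dist, 1.0), np.inf)
    np.fill_diagonal(inv, 0.0)
    mean_pow = (inv**dim).sum(axis=1) / (n - 1)
    with np.errstate(divide="ignore"):
        core = np.where(np.isinf(mean_pow), 0.0, mean_pow ** (-1.0 / dim))
    return core


def _mst_edges(weight_matrix: np.ndarray) -> list[tuple[int, int, float]]:
    """Prim MST with a canonical tie-break.

    Mutual-reachability graphs are full of exact ties (many pairs share the
    same dominating core distance), and DSC/DSPC depend on *which* MST is
    chosen, so the edge picked at every step is the minimum-weight crossing
    edge with the lexicographically smallest (min node, max node) pair.
    """
    w = np.asarray(weight_matrix, dtype=np.float64)
    n = w.shape[0]
    edges: list[tuple[int, int, float]] = []
    best_w = w[0].copy()  # cheapest crossing weight per out-of-tree node
    best_i = np.zeros(n, dtype=int)  # tree endpoint achieving it
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    for _ in range(n - 1):
        out = np.flatnonzero(~in_tree)
        lo = np.minimum(best_i[out], out)
        hi = np.maximum(best_i[out], out)
        j = out[np.lexsort((hi, lo, best_w[out]))[0]]
        edges.append((int(best_i[j]), int(j), float(best_w[j])))
        in_tree[j] = True
        still_out = np.flatnonzero(~in_tree)
        wj = w[j, still_out]
        better = wj < best_w[still_out]
        tie = wj == best_w[still_out]
        if np.any(tie):
            cand_lo = np.minimum(j, still_out)
            cand_hi = np.maximum(j, still_out)
            cur_lo = np.minimum(best_i[still_out], still_out)
            cur_hi = np.maximum(best_i[still_out], still_out)
            tie &= (cand_lo < cur_lo) | ((cand_lo == cur_lo) & (cand_hi < cur_hi))
        upd = better | tie
        best_w[still_out[upd]] = wj[upd]
        best_i[still_out[upd]] = j
    return edges


def dbcv(points: np.ndarray, labels: np.ndarray) -> float:
    """DBCV index of a labelling of ``points`` (label -1 = noise).

    Raises
    ------
    UndefinedDBCVError
        If fewer than two clusters have at least two members.
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if labels.shape[0] != points.shape[0]:
        raise ValueError("labels length must match number of points")
    n_total = points.shape[0]
    dim = points.shape[1]

    cluster_ids = [c for c in np.unique(labels) if c != NOISE]
    members = {c: np.flatnonzero(labels == c) for c in cluster_ids}
    valid = [c for c in cluster_ids if members[c].size >= 2]
    if len(valid) < 2:
        raise UndefinedDBCVError(
            f"DBCV undefined: {len(valid)} cluster(s) of size >= 2 (need >= 2)"
        )

    core: dict[int, np.ndarray] = {}
    sparseness: dict[int, float] = {}
    internal: dict[int, np.ndarray] = {}
    for c in valid:
        idx = members[c]
        dist = cdist(points[idx], points[idx])
        core_c = _all_points_core_distances(dist, dim)
        mrd = np.maximum(dist, np.maximum.outer(core_c, core_c))
        np.fill_diagonal(mrd, 0.0)
        edges = _mst_edges(mrd)
        degree = np.zeros(idx.size, dtype=int)
        for i, j, _ in edges:
            degree[i] += 1
            degree[j] += 1
        internal_local = np.flatnonzero(degree > 1)
        internal_edges = [w for i, j, w in edges if degree[i] > 1 and degree[j] > 1]
        sparseness[c] = max(internal_edges) if internal_edges else max(
            (w for _, _, w in edges), default=0.0
        )
        internal[c] = idx[internal_local] if internal_local.size else idx
        core[c] = core_c

    core_by_point = np.zeros(n_total)
    for c in valid:
        core_by_point[members[c]] = core[c]

    separation: dict[int, float] = {}
    for c in valid:
        best = np.inf
        for other in valid:
            if other == c:
                continue
            a, b = internal[c], internal[other]
            d_ab = cdist(points[a], points[b])
            mrd_ab = np.maximum(
                d_ab, np.maximum.outer(core_by_point[a], core_by_point[b])
            )
            best = min(best, float(mrd_ab.min()))
        separation[c] = best

    score = 0.0
    for c in valid:
        sep, spr = separation[c], sparseness[c]
        denom = max(sep, spr)
        validity = 0.0 if denom == 0 else (sep - spr) / denom
        score += (members[c].size / n_total) * validity
    return float(score)


def dbcv_or_none(points: np.ndarray, labels: np.ndarray) -> float | None:
    """Like :func:`dbcv` but returns ``None`` for undefined clusterings."""
    try:
        return dbcv(points, labels)
    except UndefinedDBCVError:
        return None
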