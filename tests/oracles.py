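"""Independent brute-force oracles used by the test suite.

Deliberately naive (explicit Python loops, naive Prim MST, exact rational
enumeration) and written without reference to the package implementations
they check.
"""

from __future__ import annotations

import math
from fractions import Fraction


# --- DBCV, straight from the published definition -------------------------

def _euclid(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _prim_mst(weights):
    """Naive Prim on a dense symmetric matrix; returns list of (i, j, w).

    Ties (ubiquitous in mutual-reachability graphs) are broken canonically:
    the minimum-weight crossing edge with the lexicographically smallest
    (min node, max node) pair is taken at every step.
    """
    n = len(weights)
    in_tree = [0]
    edges = []
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j in in_tree:
                    continue
                key = (weights[i][j], min(i, j), max(i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        edges.append((best[1], best[2], best[0][0]))
        in_tree.append(best[2])
    return edges


def brute_force_dbcv(points, labels):
    """DBCV by direct evaluation of the published formulas.

    All-points core distance, mutual reachability, per-cluster MST with
    internal-edge sparseness and internal-node separation, size-weighted sum
    over clusters of size >= 2 with the total sample count (noise included)
    in the denominator.  Returns None when fewer than two clusters have at
    least two members.
    """
    points = [list(map(float, p)) for p in points]
    labels = list(labels)
    n_total = len(points)
    dim = len(points[0])
    clusters = sorted({c for c in labels if c != -1})
    members = {c: [i for i, l in enumerate(labels) if l == c] for c in clusters}
    valid = [c for c in clusters if len(members[c]) >= 2]
    if len(valid) < 2:
        return None

    core = {}
    for c in valid:
        idx = members[c]
        for i in idx:
            acc = 0.0
            for j in idx:
                if i == j:
                    continue
                d = _euclid(points[i], points[j])
                acc = math.inf if d == 0 else acc + (1.0 / d) ** dim
            core[i] = 0.0 if math.isinf(acc) else (acc / (len(idx) - 1)) ** (-1.0 / dim)

    def mrd(i, j):
        return max(core[i], core[j], _euclid(points[i], points[j]))

    sparseness = {}
    internal_nodes = {}
    for c in valid:
        idx = members[c]
        w = [[mrd(a, b) if a != b else 0.0 for b in idx] for a in idx]
        edges = _prim_mst(w)
        degree = [0] * len(idx)
        for i, j, _ in edges:
            degree[i] += 1
            degree[j] += 1
        internal_local = [i for i in range(len(idx)) if degree[i] > 1]
        internal_edges = [wt for i, j, wt in edges if degree[i] > 1 and degree[j] > 1]
        if internal_edges:
            sparseness[c] = max(internal_edges)
        else:
            sparseness[c] = max(wt for _, _, wt in edges)
        internal_nodes[c] = [idx[i] for i in internal_local] or list(idx)

    score = 0.0
    for c in valid:
        sep = min(
            mrd(a, b)
            for other in valid if other != c
            for a in internal_nodes[c]
            for b in internal_nodes[other]
        )
        spr = sparseness[c]
        denom = max(sep, spr)
        validity = 0.0 if denom == 0 else (sep - spr) / denom
        score += len(members[c]) / n_total * validity
    return score


# --- Fisher two-tailed p by exact hypergeometric enumeration ---------------

def enumerate_fisher_two_tailed(k, n, K, N):
    """Exact two-tailed Fisher p: sum hypergeometric outcomes with
    probability <= that of the observed table (as exact rationals)."""
    lo, hi = max(0, n + K - N), min(n, K)
    probs = {
        x: Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
        for x in range(lo, hi + 1)
    }
    observed = probs[k]
    return float(sum(p for p in probs.values() if p <= observed))


# --- BH step-up executed literally -----------------------------------------

def stepup_bh(pvals):
    """Benjamini-Hochberg step-up, executed from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted
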