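"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the library's own code paths: plain loops and
first-principles formulas only.
"""

from __future__ import annotations

import itertools

import numpy as np


def cooccurrence_counts(mask: np.ndarray, lags: set[int]):
    """Triple loop over (gene, p, q, t, lag): the definitional count of
    genes supporting each (p, q, t, t+lag) connection.

    Returns dict (p_idx, q_idx, t, t+lag) -> set of gene indices; lag-0
    pairs use p_idx < q_idx.
    """
    n_genes, n_phen, n_time = mask.shape
    out: dict[tuple[int, int, int, int], set[int]] = {}
    for g in range(n_genes):
        for x in lags:
            for t in range(n_time - x):
                for p in range(n_phen):
                    for q in range(n_phen):
                        if p == q:
                            continue
                        if x == 0 and p > q:
                            continue
                        if mask[g, p, t] and mask[g, q, t + x]:
                            out.setdefault((p, q, t, t + x), set()).add(g)
    return out


def quartile(values, q: float) -> float:
    """Sort-based percentile with linear interpolation between order
    statistics: the value at fractional rank q * (n - 1)."""
    xs = sorted(float(v) for v in values)
    rank = q * (len(xs) - 1)
    lo = int(rank)
    hi = min(lo + 1, len(xs) - 1)
    frac = rank - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def best_lane_order(weights: np.ndarray):
    """Exhaustive search over all permutations; returns (best_score,
    best_order)."""
    k = weights.shape[0]
    best_score, best_order = -1.0, None
    for perm in itertools.permutations(range(k)):
        score = sum(weights[perm[i], perm[i + 1]] for i in range(k - 1))
        if score > best_score:
            best_score, best_order = score, perm
    return best_score, best_order


def adjacency_score(order, weights: np.ndarray) -> float:
    return float(sum(weights[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _point_dist(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    d = a - b
    if metric == "euclidean":
        return float(np.sqrt((d**2).sum()))
    return float(np.abs(d).sum())


def naive_linkage(matrix: np.ndarray, method: str, metric: str):
    """O(n^3) agglomerative clustering from first principles.

    Cluster-to-cluster distance is recomputed from all member point pairs
    at every step (min / mean / max for single / average / complete), so
    no Lance-Williams update formula is shared with the implementation
    under test.  Returns [(id_a, id_b, height)] with singleton ids 0..n-1
    and merged ids n, n+1, ... in creation order.
    """
    n = matrix.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dists = [
                _point_dist(matrix[i], matrix[j], metric)
                for i in clusters[a]
                for j in clusters[b]
            ]
            if method == "single":
                d = min(dists)
            elif method == "complete":
                d = max(dists)
            else:
                d = sum(dists) / len(dists)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def variance_explained_2(matrix: np.ndarray) -> float:
    """Fraction of total variance carried by the top two eigenvectors of
    the covariance matrix (full eigendecomposition)."""
    centered = matrix - matrix.mean(axis=0)
    cov = centered.T @ centered
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    total = eig.sum()
    if total == 0:
        return 1.0
    return float(eig[:2].sum() / total)
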