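"""Profile analytics: heat-map clustering, succession-profile encoding,
k-means classing and 2-component projection.

Prominence profiles (one phenotype label or None per time point) are
encoded as one-hot vectors of length ``n_timepoints * n_phenotypes`` — a
None entry becomes an all-zero block — so that Euclidean geometry on the
encodings corresponds to Hamming distance on the profiles (squared
distance = 2 x Hamming).  K-means on these encodings groups genes with
similar phenotypic successions; a 2-component PCA gives the standard
scatter view of the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .errors import DataValueError
from .events import ProminenceProfile

_LINKAGES = ("single", "average", "complete")
_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass
class ClusterResult:
    """Row/column leaf orders plus the row merge history.

    ``row_merges`` lists ``(cluster_a, cluster_b, height)`` triples in
    merge order; singleton clusters are numbered 0..n-1 in input order and
    merged clusters n, n+1, ... in creation order.
    """

    row_order: list[int]
    col_order: list[int]
    row_merges: list[tuple[int, int, float]]
    col_merges: list[tuple[int, int, float]]


def _leaf_order(z: np.ndarray, n: int) -> list[int]:
    # traversal rule: earlier-created (smaller-id) child first
    if n == 1:
        return [0]
    children = {n + i: (int(z[i, 0]), int(z[i, 1])) for i in range(len(z))}
    order: list[int] = []
    stack = [n + len(z) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            a, b = children[node]
            first, second = (a, b) if a < b else (b, a)
            stack.append(second)
            stack.append(first)
    return order


def _cluster_rows(matrix: np.ndarray, method: str, metric: str):
    n = matrix.shape[0]
    if n == 1:
        return [0], []
    z = linkage(pdist(matrix, metric=_METRICS[metric]), method=method)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return _leaf_order(z, n), merges


def hier_cluster(matrix: np.ndarray, method: str = "average", metric: str = "euclidean") -> ClusterResult:
    """Agglomerative clustering of a matrix's rows and columns.

    ``method`` is one of single/average/complete, ``metric`` euclidean or
    manhattan.  The merge history follows the standard Lance-Williams
    scheme; leaf order traverses each dendrogram node's earlier-created
    subtree first.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise DataValueError("cannot cluster an empty matrix")
    if method not in _LINKAGES:
        raise DataValueError(f"linkage must be one of {_LINKAGES}, got {method!r}")
    if metric not in _METRICS:
        raise DataValueError(
            f"metric must be one of {tuple(_METRICS)}, got {metric!r}"
        )
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    row_order, row_merges = _cluster_rows(matrix, method, metric)
    col_order, col_merges = _cluster_rows(matrix.T, method, metric)
    return ClusterResult(row_order, col_order, row_merges, col_merges)


@dataclass
class ProfileEncoding:
    """One-hot succession encodings: one row per gene, ``n * P`` columns in
    phenotype-within-time order."""

    genes: list[str]
    phenotypes: list[str]
    n_timepoints: int
    matrix: np.ndarray

    def row(self, gene: str) -> np.ndarray:
        return self.matrix[self.genes.index(gene)]


def encode_profiles(
    profiles: ProminenceProfile, phenotypes: list[str] | None = None
) -> ProfileEncoding:
    """Encode each gene's prominence sequence as concatenated one-hot time
    blocks (None -> all-zero block).  Column order is time-major, phenotype
    index within each block."""
    phenotypes = list(phenotypes if phenotypes is not None else profiles.phenotypes)
    pi = {p: i for i, p in enumerate(phenotypes)}
    n = profiles.n_timepoints
    mat = np.zeros((len(profiles.genes), n * len(phenotypes)))
    for gi, gene in enumerate(profiles.genes):
        for t, entry in enumerate(profiles.entries[gene]):
            if entry is not None:
                mat[gi, t * len(phenotypes) + pi[entry]] = 1.0
    return ProfileEncoding(list(profiles.genes), phenotypes, n, mat)


def kmeans_profiles(
    encoding: ProfileEncoding, k: int = 4, seed: int = 0, restarts: int = 10
) -> np.ndarray:
    """K-means classing of the encoded profiles.

    Lloyd iteration with k-means++ seeding, best of ``restarts`` runs by
    within-cluster sum of squares; fully deterministic for a fixed seed.
    ``k`` defaults to 4 classes.
    """
    if restarts < 1:
        raise DataValueError("restarts must be >= 1")
    distinct = np.unique(encoding.matrix, axis=0).shape[0]
    if k > distinct:
        raise DataValueError(
            f"k={k} exceeds the number of distinct profile vectors ({distinct})"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    return km.fit_predict(encoding.matrix)


def pca2(encoding: ProfileEncoding | np.ndarray) -> np.ndarray:
    """Project centered encodings onto the top two principal axes.

    Sign convention: the first nonzero loading of each axis is positive,
    so the projection is reproducible across runs and platforms.
    """
    mat = encoding.matrix if isinstance(encoding, ProfileEncoding) else np.asarray(encoding, dtype=float)
    if mat.shape[0] < 2:
        raise DataValueError("PCA requires at least 2 genes")
    centered = mat - mat.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt[:2] if vt.shape[0] >= 2 else np.vstack([vt, np.zeros_like(vt[:1])])
    for i in range(axes.shape[0]):
        nz = np.nonzero(np.abs(axes[i]) > 1e-12)[0]
        if nz.size and axes[i, nz[0]] < 0:
            axes[i] = -axes[i]
    return centered @ axes.T
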