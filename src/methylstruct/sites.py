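"""Site clustering from DAPC score centroids.

Sites are summarized by the centroid of their individuals' discriminant
scores, clustered by UPGMA (unweighted average linkage) on Euclidean
distances, and the number of clusters is chosen by maximizing the Pearson
correlation between the original distance matrix and the binary
different-cluster matrix of each candidate partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree
from scipy.spatial.distance import pdist, squareform

from .dapc import DapcModel

__all__ = [
    "SiteClustering",
    "site_centroids",
    "upgma",
    "cophenetic_matrix",
    "optimal_partition",
    "cluster_sites",
    "to_newick",
]


@dataclass
class SiteClustering:
    sites: list
    centroids: np.ndarray  # sites x retained discriminant axes
    distances: np.ndarray  # square Euclidean-distance matrix
    linkage: np.ndarray  # scipy-format (n-1, 4) UPGMA merge table
    k_candidates: np.ndarray
    correlations: np.ndarray  # distance / binary-partition Pearson r per k
    selected_k: int
    labels: np.ndarray  # site -> cluster id at selected k


def site_centroids(model: DapcModel, site_labels=None) -> tuple[list, np.ndarray]:
    """Unweighted mean of individual scores per site, on the model's axes."""
    labels = model.labels if site_labels is None else np.asarray(site_labels)
    if len(labels) != model.scores.shape[0]:
        raise ValueError("site labels must match the scored individuals")
    sites = sorted(set(labels.tolist()))
    cent = np.vstack([model.scores[labels == s].mean(axis=0) for s in sites])
    return sites, cent


def upgma(dist: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration of a square distance matrix.

    Returns a scipy-format linkage table.  Exact ties are broken by merging
    the lexicographically smallest cluster-id pair, so the merge order is
    fully deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.abs(np.diag(dist)).max() > 0:
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("UPGMA needs at least 3 items")

    D = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = D[(min(a, b), max(a, b))]
                key = (d, min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        d, a, b = best
        new_size = sizes[a] + sizes[b]
        Z[step] = [a, b, d, new_size]
        active = [c for c in active if c not in (a, b)]
        for c in active:
            da = D[(min(a, c), max(a, c))]
            db = D[(min(b, c), max(b, c))]
            D[(min(next_id, c), max(next_id, c))] = (
                sizes[a] * da + sizes[b] * db
            ) / new_size
        sizes[next_id] = new_size
        active.append(next_id)
        next_id += 1
    return Z


def cophenetic_matrix(Z: np.ndarray) -> np.ndarray:
    from scipy.cluster.hierarchy import cophenet

    return squareform(cophenet(Z))


def optimal_partition(
    Z: np.ndarray,
    dist: np.ndarray,
    k_range: range | None = None,
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Choose the tree cut maximizing the distance/partition correlation.

    For each candidate k the tree is cut into k clusters and the binary
    matrix coding 1 for between-cluster pairs is correlated (Pearson, upper
    triangle) with the original distances; the coding makes the correlation
    positive for structure-respecting partitions.  k = 1 and k = n are
    excluded (constant binary matrix).  Ties go to the smaller k.

    Returns ``(selected_k, labels, k_candidates, correlations)``.
    """
    n = dist.shape[0]
    if k_range is None:
        k_range = range(2, n)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no valid candidate (needs 2..n-1)")
    iu = np.triu_indices(n, k=1)
    dvec = dist[iu]
    corrs = np.empty(len(ks))
    labelings = []
    for i, k in enumerate(ks):
        lab = cut_tree(Z, n_clusters=k).ravel()
        b = (lab[:, None] != lab[None, :]).astype(float)[iu]
        corrs[i] = np.corrcoef(dvec, b)[0, 1]
        labelings.append(lab)
    best = int(np.argmax(corrs))  # argmax returns the first (smallest k) on ties
    return ks[best], labelings[best], np.asarray(ks), corrs


def cluster_sites(model: DapcModel, site_labels=None) -> SiteClustering:
    """End-to-end: centroids -> Euclidean distances -> UPGMA -> optimal k."""
    sites, cent = site_centroids(model, site_labels)
    dist = squareform(pdist(cent))
    Z = upgma(dist)
    k, labels, ks, corrs = optimal_partition(Z, dist)
    return SiteClustering(
        sites=sites,
        centroids=cent,
        distances=dist,
        linkage=Z,
        k_candidates=ks,
        correlations=corrs,
        selected_k=k,
        labels=labels,
    )


def to_newick(Z: np.ndarray, leaf_names: list) -> str:
    """Newick string with ultrametric branch lengths (half the merge-height
    difference between parent and child node)."""
    n = Z.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    parts = {i: str(leaf_names[i]) for i in range(n)}
    for step in range(n - 1):
        a, b, h, _ = Z[step]
        a, b = int(a), int(b)
        node = n + step
        heights[node] = h
        la = (h - heights[a]) / 2.0
        lb = (h - heights[b]) / 2.0
        parts[node] = f"({parts[a]}:{la:.6g},{parts[b]}:{lb:.6g})"
    return parts[2 * n - 2] + ";"
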