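"""Clustering of decoy ensembles and representative-model selection.

Clustering operates on a dissimilarity matrix (use
:func:`decoyclust.matrix.to_distance` first for similarity measures).
Two families are provided:

* Hierarchical agglomerative clustering with single, maximum (complete)
  or average linkage, cut to exactly k clusters.
* K-means (Lloyd's algorithm) on the rows of the distance matrix — each
  model's feature vector is its distances to all models, which keeps the
  method measure-agnostic and coordinate-free.

A representative model for the whole ensemble is picked by min(<R>/f):
<R> is the mean pairwise distance inside a cluster, f its fraction of the
ensemble, so large tight clusters win. Within the winning cluster the
medoid (member with minimal mean distance to co-members) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .models import ConfigError, InputError
from .matrix import SimilarityMatrix

__all__ = [
    "ClusterStats",
    "ClusterResult",
    "hierarchical_cluster",
    "kmeans_cluster",
    "select_representative",
    "cluster_stats",
]

_LINKAGE_METHODS = {"single": "single", "maximum": "complete", "average": "average"}

#: CLI method codes, kept for fidelity with the original invocation style.
METHOD_CODES = {0: "kmeans", 1: "single", 2: "maximum", 3: "average"}


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster summary used for representative selection."""

    label: int
    size: int
    fraction: float          # f = size / N
    mean_internal: float     # <R>: mean within-cluster pair distance; 0 for singletons
    criterion: float         # <R> / f
    representative: int      # medoid index into the ensemble


@dataclass(frozen=True)
class ClusterResult:
    """A partition of the ensemble plus per-cluster statistics."""

    labels: np.ndarray
    k: int
    method: str
    per_cluster: tuple
    inertia: float | None = None
    inertia_history: tuple | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)


def _check_distance_matrix(distances: SimilarityMatrix) -> np.ndarray:
    v = distances.values
    if np.any(np.diag(v) != 0.0):
        raise InputError(
            "distance matrix has a non-zero diagonal; similarity scores must "
            "be converted with to_distance() before clustering"
        )
    if not np.allclose(v, v.T):
        raise InputError("distance matrix is not symmetric")
    return v


def cluster_stats(labels: np.ndarray, distances: SimilarityMatrix) -> tuple:
    """Compute (size, f, <R>, <R>/f, medoid) for every cluster label."""
    v = distances.values
    labels = np.asarray(labels)
    n = len(labels)
    if n != distances.n:
        raise InputError("labels and distance matrix disagree on model count")
    stats = []
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        size = len(members)
        f = size / n
        sub = v[np.ix_(members, members)]
        if size == 1:
            mean_r = 0.0
            representative = int(members[0])
        else:
            iu = np.triu_indices(size, k=1)
            mean_r = float(np.mean(sub[iu]))
            # medoid: minimal mean distance to co-members; argmin takes the
            # lowest index on ties
            mean_to_others = sub.sum(axis=1) / (size - 1)
            representative = int(members[int(np.argmin(mean_to_others))])
        stats.append(ClusterStats(label=int(label), size=size, fraction=f,
                                  mean_internal=mean_r, criterion=mean_r / f,
                                  representative=representative))
    return tuple(stats)


def hierarchical_cluster(distances: SimilarityMatrix, linkage_method: str,
                         k: int) -> ClusterResult:
    """Agglomerative clustering under single/maximum/average linkage.

    The merge tree is cut to exactly ``k`` clusters. Labels are renumbered
    to 0..k-1 in order of first appearance, so the result is independent
    of internal dendrogram numbering.
    """
    if linkage_method not in _LINKAGE_METHODS:
        raise ConfigError(
            f"unknown linkage {linkage_method!r}; choose from "
            f"{sorted(_LINKAGE_METHODS)}"
        )
    v = _check_distance_matrix(distances)
    n = distances.n
    if not 1 <= k <= n:
        raise InputError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        labels = np.zeros(1, dtype=np.int64)
    else:
        condensed = squareform(v, checks=False)
        Z = linkage(condensed, method=_LINKAGE_METHODS[linkage_method])
        labels = cut_tree(Z, n_clusters=k).ravel()
    labels = _canonical_labels(labels)
    return ClusterResult(labels=labels, k=int(len(np.unique(labels))),
                         method=linkage_method,
                         per_cluster=cluster_stats(labels, distances))


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber labels to 0,1,... in order of first appearance."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=np.int64)
    for idx, lab in enumerate(labels):
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[idx] = mapping[lab]
    return out


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int) -> tuple:
    """One Lloyd run from k distinct random rows; returns labels, WCSS history."""
    n = len(X)
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1, dtype=np.int64)
    history = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)  # lowest index wins ties
        # re-seed empty clusters with the worst-fit point (deterministic)
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmax(d2[np.arange(n), new_labels]))
                centers[c] = X[worst]
                new_labels[worst] = c
        history.append(float(((X - centers[new_labels]) ** 2).sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = X[labels == c]
            if len(members):
                centers[c] = members.mean(axis=0)
    wcss = float(((X - centers[labels]) ** 2).sum())
    return labels, wcss, tuple(history)


def kmeans_cluster(distances: SimilarityMatrix, k: int, seed: int = 0,
                   restarts: int = 10, max_iter: int = 300) -> ClusterResult:
    """K-means over distance-matrix rows, best of ``restarts`` by WCSS.

    Fully deterministic given ``seed``: restarts draw their initial
    centers from one seeded generator in a fixed order, and ties in the
    objective keep the earlier restart.
    """
    v = _check_distance_matrix(distances)
    n = distances.n
    if not 1 <= k <= n:
        raise InputError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        labels, wcss, history = _lloyd(v, k, rng, max_iter)
        if best is None or wcss < best[1]:
            best = (labels, wcss, history)
    labels = _canonical_labels(best[0])
    return ClusterResult(labels=labels, k=int(len(np.unique(labels))),
                         method="kmeans",
                         per_cluster=cluster_stats(labels, distances),
                         inertia=best[1], inertia_history=best[2])


def select_representative(result: ClusterResult,
                          distances: SimilarityMatrix) -> int:
    """Ensemble representative by min(<R>/f), then the winning medoid.

    The winning cluster minimizes mean-internal-distance over ensemble
    fraction; ties go to the lowest cluster label, and the medoid rule
    breaks its own ties by lowest model index.
    """
    if not result.per_cluster:
        raise InputError("empty clustering result")
    if len(result.labels) != distances.n:
        raise InputError("clustering result and distance matrix disagree")
    winner = min(result.per_cluster, key=lambda s: (s.criterion, s.label))
    return winner.representative
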