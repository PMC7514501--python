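"""Restarted K-means and subject-consensus clustering of feature matrices.

Each subject's feature matrix (rows = ROIs) is clustered with classical
Lloyd K-means: K distinct rows drawn uniformly as initial centroids, hard
assignment by squared Euclidean distance, centroid update by cluster means,
iterated until assignments stop changing; among independent restarts the
partition with the lowest total within-cluster squared distance wins.
Subject partitions are combined through binary co-cluster adjacency
matrices whose subject average (the group adjacency, entry = fraction of
subjects co-clustering a ROI pair) is itself re-clustered to give the
consensus partition.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterResult",
    "kmeans_cluster",
    "build_adjacency",
    "group_adjacency",
    "group_cluster",
    "validity_curve",
    "elbow_k",
]

MAX_ITER = 300


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    """Best-of-restarts K-means outcome.

    ``labels`` are 0-based cluster indices per row; ``within_distance`` is
    the total squared Euclidean distance of rows to their assigned centroids
    (the objective Lloyd minimizes).
    """

    labels: np.ndarray
    centroids: np.ndarray
    within_distance: float
    n_restarts_used: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _lloyd(features: np.ndarray, init_centroids: np.ndarray,
           trace: list | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run from given centroids until assignments stabilize.

    Ties go to the lowest cluster index (argmin behaviour).  An emptied
    cluster is repaired by moving the row currently farthest from its
    centroid into it.
    """
    centroids = init_centroids.copy()
    k = centroids.shape[0]
    labels = None
    for _ in range(MAX_ITER):
        d2 = cdist(features, centroids, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)
        # repair empty clusters deterministically
        for c in range(k):
            if not np.any(new_labels == c):
                assigned = d2[np.arange(len(new_labels)), new_labels]
                # only take rows from clusters that would not empty in turn
                counts = np.bincount(new_labels, minlength=k)
                candidates = np.flatnonzero(counts[new_labels] > 1)
                far = candidates[np.argmax(assigned[candidates])]
                new_labels[far] = c
        if trace is not None:
            trace.append(float(d2[np.arange(len(new_labels)), new_labels].sum()))
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = features[labels == c].mean(axis=0)
    else:
        warnings.warn(f"K-means did not stabilize within {MAX_ITER} iterations")
    d2 = cdist(features, centroids, metric="sqeuclidean")
    within = float(d2[np.arange(len(labels)), labels].sum())
    return labels, centroids, within


def kmeans_cluster(features: np.ndarray, k: int, n_restarts: int = 500,
                   seed: int | np.random.Generator = 0) -> ClusterResult:
    """Best-of-``n_restarts`` Lloyd K-means with random-row initialization.

    Each restart draws K distinct rows uniformly without replacement as the
    initial centroids.  Deterministic given ``seed``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D rows x features matrix")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    distinct = np.unique(features, axis=0)
    if k > len(distinct):
        raise ValueError(f"K={k} exceeds the {len(distinct)} distinct rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        while True:
            idx = rng.choice(len(features), size=k, replace=False)
            init = features[idx]
            if len(np.unique(init, axis=0)) == k:
                break
        labels, centroids, within = _lloyd(features, init)
        if best is None or within < best[2]:
            best = (labels, centroids, within)
    labels, centroids, within = best
    return ClusterResult(labels=labels, centroids=centroids,
                         within_distance=within, n_restarts_used=n_restarts)


def build_adjacency(labels: Sequence[int]) -> np.ndarray:
    """Binary co-cluster matrix: entry (i, j) = 1 iff labels[i] == labels[j]."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    return (labels[:, None] == labels[None, :]).astype(float)


def group_adjacency(adjacencies: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of individual co-cluster matrices.

    Entry (i, j) is the fraction of subjects clustering ROIs i and j
    together; the diagonal stays 1.
    """
    if len(adjacencies) == 0:
        raise ValueError("need at least one adjacency matrix")
    shape = adjacencies[0].shape
    for a in adjacencies:
        if a.shape != shape:
            raise ValueError("adjacency matrices differ in shape")
    return np.mean(adjacencies, axis=0)


def group_cluster(group: np.ndarray, k: int, n_restarts: int = 500,
                  seed: int | np.random.Generator = 0) -> ClusterResult:
    """Cluster the rows of the group adjacency matrix (consensus step)."""
    return kmeans_cluster(group, k, n_restarts=n_restarts, seed=seed)


def validity_curve(features: np.ndarray, k_range: Sequence[int],
                   n_restarts: int = 500,
                   seed: int | np.random.Generator = 0) -> list[tuple[int, float]]:
    """Cluster validity index (within / between distance ratio) per K.

    For the best-of-restarts partition at each K: within = total squared
    distance of rows to their assigned centroid; between = total squared
    distance of rows to the centroids of all clusters they do NOT belong
    to.  The elbow of this decreasing curve marks candidate K values.
    """
    features = np.asarray(features, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for k in k_range:
        res = kmeans_cluster(features, k, n_restarts=n_restarts, seed=rng)
        d2 = cdist(features, res.centroids, metric="sqeuclidean")
        within = float(d2[np.arange(len(res.labels)), res.labels].sum())
        between = float(d2.sum() - within)
        out.append((int(k), within / between if between > 0 else 0.0))
    return out


def elbow_k(curve: Sequence[tuple[int, float]], floor: float = 1e-12) -> int:
    """Elbow of a validity curve: K with maximal discrete curvature.

    The within/between index of well-separated data decays by orders of
    magnitude before the true K and flattens after it, so curvature is
    measured on log(index) (scale-invariant; a raw second difference would
    always peak at the smallest K of a geometric decay).  Indices below
    ``floor`` are clamped before taking logs so an exact-zero within
    distance does not produce infinities.
    """
    if len(curve) < 3:
        raise ValueError("need at least three (K, index) points")
    ks = [k for k, _ in curve]
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K_range must be consecutive for curvature")
    logs = np.log(np.maximum([v for _, v in curve], floor))
    curvature = logs[:-2] - 2 * logs[1:-1] + logs[2:]
    return int(ks[1 + int(np.argmax(curvature))])
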