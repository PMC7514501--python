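"""Independent brute-force oracles used to validate the optimized code paths.

Everything here is written the slow, obvious way (explicit loops, textbook
formulas) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation: covariance over the product of SDs."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def weighted_pearson_oracle(x, y, w) -> float:
    """Weighted Pearson correlation with normalized observation weights."""
    sw = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
    my = sum(wi * yi for wi, yi in zip(w, y)) / sw
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y))
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x))
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y))
    return cov / math.sqrt(vx * vy)


def convolution_oracle(a, b):
    """Full discrete convolution by direct summation."""
    out = [0.0] * (len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return out


def sampen_oracle(x, m: int = 2, epsilon: float = 0.2) -> float:
    """Double-loop sample entropy: count template matches pair by pair.

    C_i^m averages Heaviside(r - Chebyshev distance) over the other
    m-vectors; U^m and U^{m+1} are the means of those match fractions, and
    SampEn = -ln(U^{m+1} / U^m).  Theta(0) = 1: distance exactly r matches.
    """
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = epsilon * sd

    def u(dim: int) -> float:
        n_vec = n - dim + 1
        vectors = [x[i:i + dim] for i in range(n_vec)]
        total = 0  # exact integer match count over all ordered pairs
        for i in range(n_vec):
            for j in range(n_vec):
                if j == i:
                    continue
                dist = max(abs(a - b) for a, b in zip(vectors[i], vectors[j]))
                if dist <= r:
                    total += 1
        return total / n_vec / (n_vec - 1)

    um = u(m)
    um1 = u(m + 1)
    if um1 == 0:
        return float("inf")
    return -math.log(um1 / um)


def exhaustive_kmeans_oracle(points: np.ndarray, k: int) -> float:
    """Global minimum within-cluster squared distance over all k-partitions.

    Enumerates every surjective assignment of points to k clusters (label
    permutations included; harmless for the optimum).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    best = math.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        labels = np.asarray(assignment)
        within = 0.0
        for c in range(k):
            rows = points[labels == c]
            centroid = rows.mean(axis=0)
            within += float(((rows - centroid) ** 2).sum())
        if within < best:
            best = within
    return best


def co_cluster_oracle(labels) -> np.ndarray:
    """Pairwise label-equality matrix by double loop."""
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = 1.0 if labels[i] == labels[j] else 0.0
    return out


def confusion_oracle(cluster_labels, network_labels, n_networks, n_clusters) -> np.ndarray:
    """Network x cluster co-occurrence counts by double loop."""
    out = np.zeros((n_networks, n_clusters), dtype=int)
    for net, clu in zip(network_labels, cluster_labels):
        out[net, clu] += 1
    return out


def squared_distance_oracle(a, b) -> float:
    """Sum of squared element-wise differences by double loop."""
    total = 0.0
    for i in range(len(a)):
        for j in range(len(a[i])):
            total += (float(a[i][j]) - float(b[i][j])) ** 2
    return total
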