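"""Agreement between cluster partitions and reference functional networks.

Clusters are matched to networks by an optimal bijective assignment on the
network x cluster confusion table; per matched pair the package reports the
overlap ratio (fraction of the cluster's ROIs inside its network — the
cluster's precision) and the consistency ratio (intersection over union,
i.e. the Jaccard index of cluster and network).  Partition-level agreement
between adjacency matrices uses the squared Euclidean distance.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "RoiTemplate",
    "ConfusionTable",
    "confusion_table",
    "match_clusters",
    "overlap_ratio",
    "consistency_ratio",
    "adjacency_distance",
    "centroid_distance_profile",
    "percent",
]


@dataclasses.dataclass(frozen=True)
class RoiTemplate:
    """ROI template: per-ROI index, name and reference network label."""

    roi_index: np.ndarray  # 1-based
    roi_name: tuple[str, ...]
    network_label: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.roi_index)
        if not (len(self.roi_name) == len(self.network_label) == n):
            raise ValueError("template columns differ in length")

    @property
    def n_rois(self) -> int:
        return len(self.roi_index)

    @property
    def networks(self) -> tuple[str, ...]:
        """Network names in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.network_label:
            seen.setdefault(lab, None)
        return tuple(seen)

    @property
    def network_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.network_label:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def labels_as_int(self) -> np.ndarray:
        order = {name: i for i, name in enumerate(self.networks)}
        return np.asarray([order[lab] for lab in self.network_label])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoiTemplate":
        df = pd.read_csv(path, sep="\t", dtype={"roi_name": str, "network_label": str})
        return cls(
            roi_index=df["roi_index"].to_numpy(),
            roi_name=tuple(df["roi_name"]),
            network_label=tuple(df["network_label"]),
        )


@dataclasses.dataclass(frozen=True)
class ConfusionTable:
    """Network x cluster ROI counts; rows are networks, columns clusters."""

    counts: np.ndarray
    networks: tuple[str, ...]
    clusters: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.networks), len(self.clusters)):
            raise ValueError("counts shape does not match labels")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def network_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfusionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df.to_numpy(dtype=int),
                   networks=tuple(df.index), clusters=tuple(df.columns))


def confusion_table(labels: Sequence[int], template: RoiTemplate) -> ConfusionTable:
    """Count ROIs in the overlap of each network with each cluster."""
    labels = np.asarray(labels)
    if len(labels) != template.n_rois:
        raise ValueError(
            f"{len(labels)} cluster labels for {template.n_rois} template ROIs"
        )
    networks = template.networks
    net_idx = template.labels_as_int()
    cluster_ids = np.unique(labels)
    counts = np.zeros((len(networks), len(cluster_ids)), dtype=int)
    for ni, ci in zip(net_idx, np.searchsorted(cluster_ids, labels)):
        counts[ni, ci] += 1
    return ConfusionTable(counts=counts, networks=networks,
                          clusters=tuple(f"cluster_{c + 1}" for c in range(len(cluster_ids))))


def match_clusters(table: ConfusionTable) -> dict[int, int]:
    """Optimal bijection cluster -> network maximizing the matched ROI count.

    Solved as a linear assignment problem; when each cluster's per-column
    argmax network is already distinct (the usual case), the result
    coincides with the greedy per-cluster argmax rule.
    """
    counts = table.counts
    if counts.shape[0] != counts.shape[1]:
        raise ValueError("matching requires a square confusion table")
    clu_idx, net_idx = linear_sum_assignment(counts.T, maximize=True)
    return {int(c): int(n) for c, n in zip(clu_idx, net_idx)}


def overlap_ratio(table: ConfusionTable, mapping: Mapping[int, int]) -> list[Fraction]:
    """Per-cluster overlap with its matched network: |C ∩ N| / |C|."""
    _check_mapping(table, mapping)
    out = []
    for c in range(len(table.clusters)):
        size = int(table.cluster_sizes[c])
        if size == 0:
            raise ValueError(f"cluster {c} is empty")
        out.append(Fraction(int(table.counts[mapping[c], c]), size))
    return out


def consistency_ratio(table: ConfusionTable, mapping: Mapping[int, int]) -> list[Fraction]:
    """Per-cluster Jaccard index with its matched network: |C ∩ N| / |C ∪ N|."""
    _check_mapping(table, mapping)
    out = []
    for c in range(len(table.clusters)):
        n = mapping[c]
        inter = int(table.counts[n, c])
        union = int(table.network_sizes[n]) + int(table.cluster_sizes[c]) - inter
        if union == 0:
            raise ValueError(f"cluster {c} and network {n} are both empty")
        out.append(Fraction(inter, union))
    return out


def _check_mapping(table: ConfusionTable, mapping: Mapping[int, int]) -> None:
    n = len(table.clusters)
    if sorted(mapping) != list(range(n)) or sorted(mapping.values()) != list(range(n)):
        raise ValueError("mapping must be a bijection over cluster/network indices")


def percent(frac: Fraction, decimals: int = 2) -> float:
    """Render a ratio as a percentage, rounding half away from zero."""
    q = Decimal(1).scaleb(-decimals)
    value = Decimal(frac.numerator) * 100 / Decimal(frac.denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def adjacency_distance(first: np.ndarray, second: np.ndarray) -> float:
    """Squared Euclidean distance between two adjacency-like matrices."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape:
        raise ValueError("matrices differ in shape")
    return float(((first - second) ** 2).sum())


def centroid_distance_profile(features: np.ndarray, result) -> tuple[np.ndarray, np.ndarray]:
    """Mean (and SD) squared distance from each cluster's rows to each centroid.

    Entry (i, j) is the mean over rows assigned to cluster j of the squared
    Euclidean distance to centroid i; for a converged K-means result the
    column-wise minimum sits on the diagonal.
    """
    features = np.asarray(features, dtype=float)
    k = result.k
    means = np.empty((k, k))
    sds = np.empty((k, k))
    for j in range(k):
        rows = features[result.labels == j]
        d2 = ((rows[:, None, :] - result.centroids[None, :, :]) ** 2).sum(axis=2)
        means[:, j] = d2.mean(axis=0)
        sds[:, j] = d2.std(axis=0)
    return means, sds
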