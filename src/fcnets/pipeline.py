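"""End-to-end orchestration: BOLD -> features -> consensus partition -> report.

For each subject the configured feature matrix is computed (static FC, or
the SampEn matrix of tapered sliding-window dynamic FC), clustered with
restarted K-means, and turned into a binary co-cluster adjacency; the
subject-averaged group adjacency is re-clustered to yield the consensus
partition, which is scored against a reference ROI template via the
confusion table, optimal cluster-network matching, and overlap/consistency
ratios.

Seeding: one master seed; subject *s* clusters with rng ``[seed, s]`` and
the group step with rng ``[seed, 2**20]`` (counter-based streams, so the
result is invariant to subject processing order).
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Sequence

import numpy as np

from .clustering import (ClusterResult, build_adjacency, group_adjacency,
                         group_cluster, kmeans_cluster)
from .connectivity import compute_dynamic_fc, compute_static_fc, make_tapered_window
from .entropy import SampEnParams, compute_sampen_matrix
from .evaluation import (ConfusionTable, RoiTemplate, confusion_table,
                         consistency_ratio, match_clusters, overlap_ratio, percent)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "subject_features"]

GROUP_STREAM = 2 ** 20  # counter reserved for the group-level clustering rng


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the consensus-clustering pipeline."""

    measurement: str = "static"  # "static" | "sampen"
    k: int = 6
    n_restarts: int = 500
    seed: int = 0
    rect_len: int = 20
    gauss_sd: float = 3.0
    effective_len: int = 21
    step: int = 1
    sampen_m: int = 2
    sampen_epsilon: float = 0.2

    def __post_init__(self) -> None:
        if self.measurement not in ("static", "sampen"):
            raise ValueError("measurement must be 'static' or 'sampen'")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclasses.dataclass(frozen=True)
class PipelineReport:
    """All pipeline artifacts for one run."""

    config: PipelineConfig
    features: tuple[np.ndarray, ...]  # per-subject B or E
    subject_results: tuple[ClusterResult, ...]
    adjacencies: tuple[np.ndarray, ...]
    group: np.ndarray
    group_result: ClusterResult
    confusion: ConfusionTable | None
    mapping: dict[int, int] | None
    overlap: list[Fraction] | None
    consistency: list[Fraction] | None

    @property
    def group_labels(self) -> np.ndarray:
        return self.group_result.labels

    def ratios_percent(self) -> dict[str, list[float]]:
        if self.overlap is None:
            raise ValueError("no template was supplied; ratios unavailable")
        return {
            "overlap": [percent(f) for f in self.overlap],
            "consistency": [percent(f) for f in self.consistency],
        }


def subject_features(bold: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Feature matrix for one subject: static FC matrix B or SampEn matrix E."""
    if config.measurement == "static":
        return compute_static_fc(bold)
    window = make_tapered_window(config.rect_len, config.gauss_sd,
                                 config.effective_len, config.step)
    stack = compute_dynamic_fc(bold, window)
    params = SampEnParams(m=config.sampen_m, epsilon=config.sampen_epsilon)
    return compute_sampen_matrix(stack, params)


def run_pipeline(bold_matrices: Sequence[np.ndarray], config: PipelineConfig,
                 template: RoiTemplate | None = None) -> PipelineReport:
    """Run the full consensus pipeline over a cohort of BOLD matrices."""
    if len(bold_matrices) == 0:
        raise ValueError("need at least one subject")
    features, results, adjacencies = [], [], []
    for s, bold in enumerate(bold_matrices):
        try:
            feats = subject_features(np.asarray(bold, dtype=float), config)
            res = kmeans_cluster(feats, config.k, config.n_restarts,
                                 seed=np.random.default_rng([config.seed, s]))
        except Exception as exc:
            raise RuntimeError(f"subject {s}: {exc}") from exc
        features.append(feats)
        results.append(res)
        adjacencies.append(build_adjacency(res.labels))
    group = group_adjacency(adjacencies)
    group_result = group_cluster(group, config.k, config.n_restarts,
                                 seed=np.random.default_rng([config.seed, GROUP_STREAM]))
    confusion = mapping = overlap = consistency = None
    if template is not None:
        confusion = confusion_table(group_result.labels, template)
        if confusion.counts.shape[0] == confusion.counts.shape[1]:
            mapping = match_clusters(confusion)
            overlap = overlap_ratio(confusion, mapping)
            consistency = consistency_ratio(confusion, mapping)
    return PipelineReport(
        config=config, features=tuple(features), subject_results=tuple(results),
        adjacencies=tuple(adjacencies), group=group, group_result=group_result,
        confusion=confusion, mapping=mapping, overlap=overlap, consistency=consistency,
    )
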