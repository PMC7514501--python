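"""Static-FC consensus clustering of the simulated cohort.

Per subject: static FC matrix B -> best-of-500-restarts K-means (K=6) ->
binary co-cluster adjacency.  Subject average -> group adjacency -> group
K-means -> consensus partition, scored against the planted template
(adjusted Rand index, overlap/consistency ratios).  Also scans K=2..12 on
the subject-averaged FC and reports the validity-curve elbow.

Writes results/static_consensus.json and results/validity_curve.tsv.
"""

import json
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from fcnets import (PipelineConfig, RoiTemplate, elbow_k, read_cohort,
                    run_pipeline, validity_curve)
from fcnets.io import write_matrix

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    cohort = read_cohort(ROOT / "scratch" / "cohort")
    template = RoiTemplate.from_tsv(ROOT / "scratch" / "cohort" / "template.tsv")
    config = PipelineConfig(measurement="static", k=6, n_restarts=500, seed=20)
    report = run_pipeline(cohort.bold, config, template)
    ari = adjusted_rand_score(cohort.true_labels, report.group_labels)

    mean_fc = np.mean(report.features, axis=0)
    curve = validity_curve(mean_fc, range(2, 13), n_restarts=100, seed=20)
    elbow = elbow_k(curve)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    write_matrix(np.asarray(curve), out / "validity_curve.tsv",
                 ["K", "validity_index"])
    summary = {
        "adjusted_rand_index": float(ari),
        "elbow_k": elbow,
        "cluster_sizes": np.bincount(report.group_labels).tolist(),
        "ratios_percent": report.ratios_percent(),
        "group_within_distance": report.group_result.within_distance,
    }
    (out / "static_consensus.json").write_text(json.dumps(summary, indent=2))
    print(f"consensus vs planted partition: ARI = {ari:.3f}")
    print(f"validity-curve elbow at K = {elbow}")
    print(json.dumps(summary["ratios_percent"], indent=2))
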