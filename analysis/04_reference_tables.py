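"""Overlap and consistency ratios of the packaged reference confusion tables.

For each measurement (static FC; SampEn of dynamic FC) the six clusters are
matched to the six functional networks by optimal assignment and the
per-cluster overlap (precision) and consistency (Jaccard) ratios are
reported as exact fractions and 2-decimal percentages.

Writes results/reference_ratios.json.
"""

import json
from pathlib import Path

from fcnets import (consistency_ratio, datasets, match_clusters, overlap_ratio,
                    percent)

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    report = {}
    for measurement in ("static", "sampen"):
        table = datasets.load_reference_confusion(measurement)
        mapping = match_clusters(table)
        overlap = overlap_ratio(table, mapping)
        consistency = consistency_ratio(table, mapping)
        report[measurement] = {
            "mapping": {table.clusters[c]: table.networks[n]
                        for c, n in mapping.items()},
            "overlap": {table.clusters[c]:
                        {"fraction": f"{f.numerator}/{f.denominator}",
                         "percent": percent(f)}
                        for c, f in enumerate(overlap)},
            "consistency": {table.clusters[c]:
                            {"fraction": f"{f.numerator}/{f.denominator}",
                             "percent": percent(f)}
                            for c, f in enumerate(consistency)},
        }
        print(f"{measurement}: overlap {[percent(f) for f in overlap]}")
        print(f"{'':>{len(measurement)}}  consistency {[percent(f) for f in consistency]}")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "reference_ratios.json").write_text(json.dumps(report, indent=2))
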