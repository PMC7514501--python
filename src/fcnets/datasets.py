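"""Packaged reference data.

* The Dosenbach 160-ROI template partitioned into the six resting-state
  functional networks (default 34, frontal-parietal 21, cingulo-opercular
  32, sensorimotor 33, occipital 22, cerebellum 18).  The packaged version
  carries network membership only; ROI names are placeholders and users may
  supply a full template TSV with real names/coordinates.
* Published confusion tables counting ROIs in the overlap between each
  functional network and each of the six K-means clusters, one table per
  measurement (static FC; SampEn of dynamic FC).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .evaluation import ConfusionTable, RoiTemplate

__all__ = ["load_reference_confusion", "dosenbach_template", "NETWORK_NAMES", "NETWORK_SIZES"]

NETWORK_NAMES = (
    "default", "frontal-parietal", "cingulo-opercular",
    "sensorimotor", "occipital", "cerebellum",
)
NETWORK_SIZES = (34, 21, 32, 33, 22, 18)


def _data_path(name: str) -> Path:
    return Path(resources.files("fcnets") / "data" / name)


def load_reference_confusion(measurement: str) -> ConfusionTable:
    """Load the packaged network x cluster confusion counts.

    ``measurement`` is ``"static"`` (clusters from static FC) or
    ``"sampen"`` (clusters from the SampEn of dynamic FC).
    """
    files = {"static": "static_fc_confusion.tsv", "sampen": "sampen_confusion.tsv"}
    if measurement not in files:
        raise ValueError(f"measurement must be one of {sorted(files)}, got {measurement!r}")
    return ConfusionTable.from_tsv(_data_path(files[measurement]))


def dosenbach_template() -> RoiTemplate:
    """The 160-ROI six-network template (membership only, synthetic names)."""
    labels = tuple(
        name for name, size in zip(NETWORK_NAMES, NETWORK_SIZES) for _ in range(size)
    )
    names = tuple(
        f"{name}_{i + 1:02d}"
        for name, size in zip(NETWORK_NAMES, NETWORK_SIZES)
        for i in range(size)
    )
    return RoiTemplate(
        roi_index=np.arange(1, len(labels) + 1),
        roi_name=names,
        network_label=labels,
    )
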