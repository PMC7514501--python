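"""TSV round-tripping for matrices (full double precision, bit-exact)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_matrix", "read_matrix"]


def write_matrix(matrix: np.ndarray, path: str | Path,
                 header: list[str] | None = None) -> None:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if header is None:
        header = [f"c{j + 1}" for j in range(matrix.shape[1])]
    with Path(path).open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in matrix:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
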