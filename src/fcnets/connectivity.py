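"""Static and sliding-window (tapered) dynamic functional connectivity.

Static FC is the plain Pearson correlation of two ROI time courses over the
whole scan.  Dynamic FC slides a tapered window (rectangle convolved with a
Gaussian) along the scan in steps of one TR and computes, per window, a
weighted Pearson correlation in which the taper acts as observation weights.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "WindowSpec",
    "DynamicFCStack",
    "compute_static_fc",
    "make_tapered_window",
    "compute_dynamic_fc",
]


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Tapered sliding-window definition.

    ``taper`` holds the nonnegative weights (normalized to sum 1) applied to
    the ``effective_len`` samples of each window; ``step`` is the slide in
    time points between consecutive windows.
    """

    rect_len: int
    gauss_sd: float
    step: int
    taper: np.ndarray
    effective_len: int

    def __post_init__(self) -> None:
        taper = np.asarray(self.taper, dtype=float)
        object.__setattr__(self, "taper", taper)
        if taper.ndim != 1 or len(taper) != self.effective_len:
            raise ValueError("taper length must equal effective_len")
        if np.any(taper < 0):
            raise ValueError("taper weights must be nonnegative")
        if abs(taper.sum() - 1.0) > 1e-12:
            raise ValueError("taper weights must sum to 1")
        if not np.allclose(taper, taper[::-1], atol=1e-12):
            raise ValueError("taper must be symmetric about its midpoint")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclasses.dataclass(frozen=True)
class DynamicFCStack:
    """Windowed correlation stack: ``values[k, i, j]`` is the FC of ROI pair
    (i, j) in window k; ``pair_series(i, j)`` is its evolution over windows."""

    values: np.ndarray  # n_windows x n_rois x n_rois
    window: WindowSpec

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def pair_series(self, i: int, j: int) -> np.ndarray:
        return self.values[:, i, j]


def compute_static_fc(bold: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of ROI columns over all time points.

    Raises if any column has zero variance (correlation undefined) or the
    series is shorter than 3 time points.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[0] < 3:
        raise ValueError("bold must be a 2-D time x ROI matrix with >= 3 time points")
    if not np.all(np.isfinite(bold)):
        raise ValueError("bold contains non-finite values")
    flat = np.flatnonzero(bold.max(axis=0) == bold.min(axis=0))
    if flat.size:
        raise ValueError(f"zero-variance ROI column(s): {flat.tolist()}")
    corr = np.corrcoef(bold, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def make_tapered_window(rect_len: int = 20, gauss_sd: float = 3.0,
                        effective_len: int = 21, step: int = 1) -> WindowSpec:
    """Build the tapered window: unit rectangle convolved with a Gaussian.

    The Gaussian density is sampled at integer offsets spanning +/- 4 SD; the
    central ``effective_len`` samples of the full convolution are retained
    and renormalized to sum 1.  When the full support and ``effective_len``
    have opposite parity there is no single centred slice; the two central
    alignments (reverses of each other) are averaged, which keeps the taper
    exactly symmetric.
    """
    if rect_len < 2:
        raise ValueError("rect_len must be >= 2")
    if gauss_sd <= 0:
        raise ValueError("gauss_sd must be > 0")
    rect = np.ones(rect_len)
    half = int(np.ceil(4 * gauss_sd))
    offsets = np.arange(-half, half + 1)
    gauss = np.exp(-0.5 * (offsets / gauss_sd) ** 2)
    gauss /= gauss.sum()
    full = np.convolve(rect, gauss)
    if effective_len > len(full) or effective_len < rect_len - 1:
        raise ValueError(
            f"effective_len must be in [{rect_len - 1}, {len(full)}], got {effective_len}"
        )
    start = (len(full) - effective_len) // 2
    taper = full[start:start + effective_len]
    taper = (taper + taper[::-1]) / 2.0  # enforce exact symmetry
    taper /= taper.sum()
    return WindowSpec(rect_len=rect_len, gauss_sd=gauss_sd, step=step,
                      taper=taper, effective_len=effective_len)


def compute_dynamic_fc(bold: np.ndarray, window: WindowSpec) -> DynamicFCStack:
    """Weighted Pearson correlation per sliding window.

    Window k covers time points ``[k*step, k*step + effective_len)``; within
    a window the taper weights define weighted means, variances and the
    covariance.  A zero weighted variance makes that ROI's correlations in
    that window 0 (with a warning) rather than aborting the whole stack.
    """
    bold = np.asarray(bold, dtype=float)
    L = window.effective_len
    if bold.ndim != 2 or bold.shape[0] < L + 2:
        raise ValueError("need at least effective_len + 2 time points")
    if not np.all(np.isfinite(bold)):
        raise ValueError("bold contains non-finite values")
    T, R = bold.shape
    w = window.taper
    n_windows = (T - L) // window.step + 1
    stack = np.empty((n_windows, R, R))
    for k in range(n_windows):
        seg = bold[k * window.step:k * window.step + L]
        mean = w @ seg
        centered = seg - mean
        cov = centered.T @ (centered * w[:, None])
        var = np.diag(cov).copy()
        bad = np.flatnonzero(var <= 0)
        if bad.size:
            warnings.warn(
                f"zero weighted variance in window {k} for ROI(s) {bad.tolist()}; "
                "their correlations set to 0"
            )
            var[bad] = 1.0
        denom = np.sqrt(np.outer(var, var))
        corr = cov / denom
        corr = (corr + corr.T) / 2.0  # remove last-ulp asymmetry of the matmul
        if bad.size:
            corr[bad, :] = 0.0
            corr[:, bad] = 0.0
        np.fill_diagonal(corr, 1.0)
        stack[k] = np.clip(corr, -1.0, 1.0)
    return DynamicFCStack(values=stack, window=window)
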