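"""Sample entropy (SampEn) of scalar series and of dynamic-FC pair series.

SampEn(x; m, r) = -ln(U^{m+1} / U^m), where U^m is the mean over all
m-point embedding vectors of the fraction of *other* vectors within
Chebyshev distance r, and U^{m+1} the analogue for (m+1)-point vectors.
The tolerance is r = epsilon * sigma_x with sigma_x the population standard
deviation of the series; a distance exactly equal to r counts as a match
(Heaviside step with theta(0) = 1).  A constant series therefore attains the
lower bound SampEn = 0; a series with no (m+1)-matches returns +inf.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = ["SampEnParams", "sample_entropy", "compute_sampen_matrix"]


@dataclasses.dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension ``m`` and tolerance fraction ``epsilon``.

    The absolute tolerance r = epsilon * sigma_x is recomputed per series.
    ``population_sd`` switches sigma_x between the population (divide-by-N,
    the usual SampEn convention, default) and the sample (N-1) estimator.
    """

    m: int = 2
    epsilon: float = 0.2
    population_sd: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _embedded_chebyshev(diff: np.ndarray, m: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all m-point embedding vectors.

    ``diff`` is the N x N matrix |x_i - x_j|; the result is
    (N-m+1) x (N-m+1) with entry (i, j) = max_t |x_{i+t} - x_{j+t}|.
    """
    n_vec = diff.shape[0] - m + 1
    out = diff[:n_vec, :n_vec].copy()
    for t in range(1, m):
        np.maximum(out, diff[t:t + n_vec, t:t + n_vec], out=out)
    return out


def sample_entropy(x: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """SampEn of a scalar series.

    Returns +inf (with a warning) when no (m+1)-point matches exist; raises
    when even the m-point match count is zero or the series is too short
    (fewer than m + 2 points).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    m = params.m
    if n < m + 2:
        raise ValueError(f"series length {n} < m + 2 = {m + 2}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    sd = x.std(ddof=0 if params.population_sd else 1)
    r = params.epsilon * sd
    diff = np.abs(x[:, None] - x[None, :])
    dist_m = _embedded_chebyshev(diff, m)
    dist_m1 = _embedded_chebyshev(diff, m + 1)
    # self-distance 0 <= r always counts; subtract it from each row count
    counts_m = (dist_m <= r).sum(axis=1) - 1
    counts_m1 = (dist_m1 <= r).sum(axis=1) - 1
    u_m = counts_m.mean() / (n - m)
    u_m1 = counts_m1.mean() / (n - m - 1)
    if u_m == 0:
        raise ValueError("no m-point matches: SampEn undefined")
    if u_m1 == 0:
        warnings.warn("no (m+1)-point matches: SampEn is +inf")
        return float("inf")
    return float(-np.log(u_m1 / u_m))


def compute_sampen_matrix(stack, params: SampEnParams = SampEnParams()) -> np.ndarray:
    """SampEn matrix E over all ROI pairs of a dynamic-FC stack.

    Entry (i, j), i != j, is the SampEn of the pair's windowed-correlation
    series d_{i,j}; the diagonal is 0 by definition (d_{i,i} is constant 1).
    Each unordered pair is computed once and mirrored.  Pairs with +inf
    entropy are reported in a warning; the matrix keeps the +inf.
    """
    values = stack.values
    n_windows, n_rois = values.shape[0], values.shape[1]
    if n_windows < params.m + 2:
        raise ValueError("too few windows for the requested embedding dimension")
    out = np.zeros((n_rois, n_rois))
    infinite_pairs = []
    for i in range(n_rois):
        for j in range(i + 1, n_rois):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                e = sample_entropy(values[:, i, j], params)
            if not np.isfinite(e):
                infinite_pairs.append((i, j))
            out[i, j] = out[j, i] = e
    if infinite_pairs:
        warnings.warn(f"+inf SampEn for ROI pairs: {infinite_pairs}")
    return out
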