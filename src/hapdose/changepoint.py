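"""Mean-shift changepoint detection for read-fraction series.

Implements optimal partitioning for a change-in-mean model under Gaussian
noise: segment cost is the residual sum of squares scaled by a robust global
noise variance, plus an MBIC-style penalty of 3*log(n) per changepoint. Two
solvers share the one objective: PELT (pruned exact linear time) and the
unpruned O(n^2) dynamic program. Because the SSE cost is subadditive, PELT's
pruning is lossless and both return identical segmentations — the unpruned
solver serves as the independent check on the pruning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Segmentation", "estimate_noise_sd", "mbic_penalty", "pelt_mean", "optimal_partition_mean"]

# median(|N(0,1)|) — scales a median absolute difference to a Gaussian sd
_PHI_75 = 0.6744897501960817


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust within-segment noise sd from successive differences.

    For iid noise, first differences are N(0, 2*sigma^2) regardless of a
    small number of mean shifts, so the median absolute successive
    difference / (sqrt(2) * 0.6745) estimates sigma robustly.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(x))) / (math.sqrt(2.0) * _PHI_75))


def mbic_penalty(n: int) -> float:
    """MBIC-style penalty for one mean parameter per extra segment."""
    return 3.0 * math.log(n)


@dataclass(frozen=True)
class Segmentation:
    """Breakpoints are indices b such that segments are x[..b) / x[b..)."""

    breakpoints: tuple
    segment_means: tuple
    segment_sizes: tuple
    penalty: float
    objective: float


def _segment_bounds(n: int, breakpoints) -> list:
    edges = [0, *breakpoints, n]
    return list(zip(edges[:-1], edges[1:]))


def _finish(x: np.ndarray, breakpoints: list, penalty: float, objective: float) -> Segmentation:
    bounds = _segment_bounds(len(x), breakpoints)
    means = tuple(float(np.mean(x[s:e])) for s, e in bounds)
    sizes = tuple(int(e - s) for s, e in bounds)
    return Segmentation(tuple(int(b) for b in breakpoints), means, sizes, penalty, objective)


def _prepare(x, penalty, min_seg, sigma):
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if min_seg < 1:
        raise ValueError("min_seg must be >= 1")
    if n < 2 * min_seg:
        raise ValueError(f"series of length {n} is shorter than 2*min_seg ({2 * min_seg})")
    if sigma is None:
        sigma = estimate_noise_sd(x)
    if penalty is None:
        penalty = mbic_penalty(n)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    # Floor sigma well below any meaningful shift but above the prefix-sum
    # cancellation error, so piecewise-constant (noise-free) input still
    # segments cleanly instead of chasing floating-point dust.
    scale = max(1.0, float(np.max(np.abs(x))))
    var = max(float(sigma), 1e-4 * scale) ** 2
    return x, n, float(penalty), s1, s2, var


def _backtrack(prev: np.ndarray, n: int) -> list:
    bps = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            bps.append(s)
        t = s
    return bps[::-1]


def pelt_mean(
    x: np.ndarray,
    penalty: float | None = None,
    min_seg: int = 1,
    sigma: float | None = None,
) -> Segmentation:
    """PELT segmentation for a change in mean.

    ``penalty`` defaults to the MBIC-style 3*log(n); ``sigma`` (noise sd used
    to scale the SSE cost) defaults to the robust successive-difference
    estimate. Zero breakpoints is a legal result.
    """
    x, n, beta, s1, s2, var = _prepare(x, penalty, min_seg, sigma)

    def seg_cost(s: np.ndarray, t: int) -> np.ndarray:
        w = t - s
        sums = s1[t] - s1[s]
        return (s2[t] - s2[s] - sums * sums / w) / var

    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=np.int64)
    cand = [0]  # candidate last-changepoint positions, ascending
    for t in range(min_seg, n + 1):
        cs = np.asarray([s for s in cand if t - s >= min_seg], dtype=np.int64)
        if len(cs) == 0:
            continue
        vals = F[cs] + seg_cost(cs, t) + beta
        k = int(np.argmin(vals))
        F[t] = vals[k]
        prev[t] = cs[k]
        # prune: s can never be optimal again if F[s] + C(s,t) > F[t]
        keep_mask = vals - beta <= F[t]
        keep = set(cs[keep_mask].tolist())
        cand = [s for s in cand if (t - s < min_seg) or (s in keep)]
        cand.append(t)  # t becomes a candidate start for later positions
    bps = _backtrack(prev, n)
    return _finish(x, bps, beta, float(F[n]))


def optimal_partition_mean(
    x: np.ndarray,
    penalty: float | None = None,
    min_seg: int = 1,
    sigma: float | None = None,
) -> Segmentation:
    """Unpruned O(n^2) optimal partitioning — same objective as
    :func:`pelt_mean`, kept as its independent exhaustive counterpart."""
    x, n, beta, s1, s2, var = _prepare(x, penalty, min_seg, sigma)
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=np.int64)
    for t in range(min_seg, n + 1):
        s = np.arange(0, t - min_seg + 1, dtype=np.int64)
        valid = np.isfinite(F[s])
        s = s[valid]
        if len(s) == 0:
            continue
        w = t - s
        sums = s1[t] - s1[s]
        cost = (s2[t] - s2[s] - sums * sums / w) / var
        vals = F[s] + cost + beta
        k = int(np.argmin(vals))
        F[t] = vals[k]
        prev[t] = s[k]
    bps = _backtrack(prev, n)
    return _finish(x, bps, beta, float(F[n]))
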