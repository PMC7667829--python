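"""Penalized change-point segmentation of log-coverage.

Binary segmentation on a piecewise-constant mean model in least squares:
a split is accepted when the within-segment sum-of-squares reduction
exceeds ``penalty * sigma2``, where ``sigma2`` is a robust estimate of
the short-range noise variance (half the median squared successive
difference, MAD-hardened).  Ties break toward fewer segments because a
split must strictly beat the penalty.
"""

from __future__ import annotations

import numpy as np

__all__ = ["binary_segmentation", "segment_means"]


def _best_split(y: np.ndarray, a: int, b: int, min_size: int):
    """Best split point of y[a:b] and its SSE gain (vectorized)."""
    seg = y[a:b]
    n = seg.size
    if n < 2 * min_size:
        return None, 0.0
    cs = np.cumsum(seg)
    cs2 = np.cumsum(seg * seg)
    total_sse = cs2[-1] - cs[-1] ** 2 / n
    k = np.arange(min_size, n - min_size + 1)  # left part size
    left_sum = cs[k - 1]
    left_sse = cs2[k - 1] - left_sum**2 / k
    right_n = n - k
    right_sum = cs[-1] - left_sum
    right_sse = (cs2[-1] - cs2[k - 1]) - right_sum**2 / right_n
    gains = total_sse - (left_sse + right_sse)
    i = int(np.argmax(gains))
    return a + int(k[i]), float(gains[i])


def estimate_noise_variance(y: np.ndarray, floor: float = 1e-3) -> float:
    """Robust per-point noise variance from successive differences."""
    d = np.diff(y)
    if d.size == 0:
        return floor
    med = float(np.median(d * d)) / 2.0
    return max(med, floor)


def binary_segmentation(
    y: np.ndarray,
    penalty: float = 30.0,
    min_size: int = 3,
    sigma2: float | None = None,
    max_segments: int = 200,
) -> list[int]:
    """Change-point positions (exclusive segment ends) of a 1-D signal.

    Returns sorted breakpoints ``[b1, ..., len(y)]`` so that segments are
    ``y[0:b1], y[b1:b2], ...``; a constant signal yields ``[len(y)]``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return []
    if sigma2 is None:
        sigma2 = estimate_noise_variance(y)
    threshold = penalty * sigma2
    breaks: list[int] = []
    stack = [(0, n)]
    while stack and len(breaks) + 1 < max_segments:
        a, b = stack.pop()
        split, gain = _best_split(y, a, b, min_size)
        if split is not None and gain > threshold:
            breaks.append(split)
            stack.append((a, split))
            stack.append((split, b))
    breaks.append(n)
    return sorted(breaks)


def segment_means(y: np.ndarray, breaks: list[int]) -> list[tuple[int, int, float]]:
    """(start, end, mean) for each segment defined by ``breaks``."""
    out = []
    a = 0
    for b in breaks:
        out.append((a, b, float(np.mean(y[a:b]))))
        a = b
    return out
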