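"""Shared 1-D peak picking: local maxima with bounds at nearest minima."""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

__all__ = ["local_maxima", "nearest_minima_bounds"]


def local_maxima(y: np.ndarray, min_height: float) -> np.ndarray:
    """Indices of local maxima above ``min_height`` (edges included)."""
    if y.size == 0 or not np.any(y > 0):
        return np.array([], dtype=int)
    padded = np.concatenate(([0.0], y, [0.0]))
    idx, _ = find_peaks(padded, height=max(min_height, np.finfo(float).tiny))
    return idx - 1


def nearest_minima_bounds(y: np.ndarray, apex: int) -> tuple[int, int]:
    """Walk outward from the apex while the signal strictly decreases."""
    i = apex
    while i > 0 and y[i - 1] < y[i]:
        i -= 1
    j = apex
    while j < y.size - 1 and y[j + 1] < y[j]:
        j += 1
    return i, j
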