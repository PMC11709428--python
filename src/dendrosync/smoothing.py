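"""Centered moving mean with shrinking edge windows (MATLAB ``movmean``)."""

from __future__ import annotations

import numpy as np


def movmean(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving mean over ``n`` samples; edges average what exists.

    For even ``n`` the window covers ``n//2`` samples back and ``n//2 - 1``
    forward, matching MATLAB's convention.
    """
    x = np.asarray(x, float)
    if n <= 1 or len(x) == 0:
        return x.copy()
    back = n // 2
    fwd = n - back - 1
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(len(x))
    lo = np.maximum(idx - back, 0)
    hi = np.minimum(idx + fwd, len(x) - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def movmean_seconds(x: np.ndarray, window_s: float, sampling_rate: float) -> np.ndarray:
    """Moving mean with the window expressed in seconds."""
    return movmean(x, max(1, int(round(window_s * sampling_rate))))
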