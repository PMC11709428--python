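"""Shared in-memory containers for traces and processed series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np


@dataclass
class RawPhotometry:
    """Two-channel demodulated photometry on a uniform time grid.

    ``f465`` is the calcium-dependent channel, ``f405`` the calcium-independent
    (isosbestic) reference; ``mask`` is 1 where acquisition was on.
    """

    time: np.ndarray  # s
    f465: np.ndarray  # a.u.
    f405: np.ndarray  # a.u.
    mask: np.ndarray  # uint8, 1 = acquisition on
    sampling_rate: float  # Hz
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.f465) == len(self.f405) == len(self.mask) == n):
            raise ValueError("RawPhotometry arrays must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class BaselineFit:
    """F_baseline(t) = a * exp(-t / tau) + c."""

    a: float
    tau_s: float
    c: float
    converged: bool = True

    def evaluate(self, time: np.ndarray) -> np.ndarray:
        if self.tau_s <= 0:
            return np.full_like(np.asarray(time, float), self.c)
        return self.a * np.exp(-np.asarray(time, float) / self.tau_s) + self.c


@dataclass
class DffTrace:
    """Baseline-corrected ΔF/F (%) series."""

    time: np.ndarray  # s
    dff: np.ndarray  # percent
    sampling_rate: float  # Hz
    baseline_fit: Optional[BaselineFit] = None
    reference_fit: Optional[Dict[str, float]] = None  # slope/intercept 405->465
    provenance: Dict[str, object] = field(default_factory=dict)
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.time) != len(self.dff):
            raise ValueError("time and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")
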