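"""Residual baseline activity: dSE excision, peak extraction, clustering.

After the surge (where present) and the dSE windows are removed, what is
left is the low-amplitude, higher-frequency baseline signal.  Peaks of this
residual are grouped into clusters wherever consecutive peaks are no more
than 420 s apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .smoothing import movmean_seconds


@dataclass
class ResidualParams:
    excision_window_s: Tuple[float, float] = (60.0, 360.0)  # -60/+360 around dSE
    threshold_pp: float = 5.0  # above the residual baseline (median)
    min_separation_s: float = 30.0
    smooth_s: float = 10.0
    cluster_gap_s: float = 420.0


@dataclass
class ResidualCluster:
    start_time: float  # s, first peak
    end_time: float  # s, last peak
    peak_times: np.ndarray
    mean_peak_amplitude: float  # dF/F %

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    @property
    def duration_min(self) -> float:
        return (self.end_time - self.start_time) / 60.0

    @property
    def intra_cluster_frequency_hz(self) -> Optional[float]:
        span = self.end_time - self.start_time
        return self.n_peaks / span if span > 0 else None


def excise_dse_windows(
    time: np.ndarray,
    dse_peak_times: Sequence[float],
    window_s: Tuple[float, float] = (60.0, 360.0),
) -> np.ndarray:
    """Boolean mask of samples excluded by the [-pre, +post] dSE windows.

    Overlapping windows merge naturally in the mask.
    """
    t = np.asarray(time)
    pre, post = window_s
    excl = np.zeros(len(t), bool)
    for p in np.sort(np.asarray(dse_peak_times, float)):
        excl |= (t >= p - pre) & (t <= p + post)
    return excl


def extract_residual_peaks(
    time: np.ndarray,
    values: np.ndarray,
    excluded: Optional[np.ndarray] = None,
    params: Optional[ResidualParams] = None,
    sampling_rate: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Residual peak times/amplitudes above baseline + threshold.

    Baseline is the median of the non-excluded (smoothed) samples; peaks
    falling inside excluded windows are dropped.
    """
    params = params or ResidualParams()
    t = np.asarray(time)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    y = movmean_seconds(np.asarray(values, float), params.smooth_s, sampling_rate)
    if excluded is None:
        excluded = np.zeros(len(t), bool)
    keep = ~excluded
    if keep.sum() == 0:
        return np.asarray([]), np.asarray([])
    baseline = float(np.median(y[keep]))
    idx, _ = find_peaks(
        y,
        height=baseline + params.threshold_pp,
        distance=max(1, int(params.min_separation_s * sampling_rate)),
    )
    idx = idx[keep[idx]]
    return t[idx], y[idx] - baseline


def cluster_and_score(
    peak_times: Sequence[float],
    peak_amplitudes: Optional[Sequence[float]] = None,
    gap_s: float = 420.0,
) -> List[ResidualCluster]:
    """Greedy segmentation: a gap > ``gap_s`` to the previous peak starts a
    new cluster (a gap of exactly ``gap_s`` stays in-cluster)."""
    t = np.asarray(peak_times, float)
    if peak_amplitudes is None:
        amps = np.zeros(len(t))
    else:
        amps = np.asarray(peak_amplitudes, float)
    order = np.argsort(t)
    t, amps = t[order], amps[order]
    clusters: List[ResidualCluster] = []
    if len(t) == 0:
        return clusters
    start = 0
    for i in range(1, len(t) + 1):
        if i == len(t) or t[i] - t[i - 1] > gap_s:
            seg = slice(start, i)
            clusters.append(
                ResidualCluster(
                    start_time=float(t[seg][0]),
                    end_time=float(t[seg][-1]),
                    peak_times=t[seg].copy(),
                    mean_peak_amplitude=float(np.mean(amps[seg])),
                )
            )
            start = i
    return clusters


def summarize_clusters(clusters: List[ResidualCluster]) -> dict:
    """Recording-level summary.  Single-peak clusters have no defined
    duration and are excluded from the duration/frequency means."""
    multi = [c for c in clusters if c.n_peaks > 1]
    return {
        "n_clusters": len(clusters),
        "n_single_peak": len(clusters) - len(multi),
        "mean_duration_min": float(np.mean([c.duration_min for c in multi])) if multi else None,
        "mean_intra_cluster_freq_hz": float(
            np.mean([c.intra_cluster_frequency_hz for c in multi])
        )
        if multi
        else None,
        "mean_peak_amplitude_pp": float(np.mean([c.mean_peak_amplitude for c in clusters]))
        if clusters
        else None,
    }
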