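"""LH pulse detection and dSE-to-LH temporal alignment.

Works on sparse tail-tip hormone series (5–10 min sampling for pulse runs,
3 h for surge runs).  The pulse rule is deliberately simple — a sample that
rises above the recent nadir by a multiple of the assay CV — because serial
mouse LH series are short and noisy; its parameters are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class LHSeries:
    """Sparse LH concentration series (ng/mL)."""

    times: np.ndarray  # s
    concentrations: np.ndarray  # ng/mL
    sampling_interval: float = 0.0  # s, nominal

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class AlignmentResult:
    """Per-dSE lags to the following LH pulse peak."""

    pairs: List[Tuple[float, float, float]]  # (dse_peak_s, lh_peak_s, lag_min)
    mean_lag_min: Optional[float]
    sem_lag_min: Optional[float]
    unmatched_dse: int
    unmatched_lh: int


def detect_lh_pulses(
    series: LHSeries,
    assay_cv: float = 0.082,
    cv_multiple: float = 6.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Detect LH pulse peaks; returns (peak_times_s, peak_amplitudes).

    A sample is a pulse peak when it exceeds both neighbours and exceeds the
    minimum of the preceding reference window — two nominal sampling
    intervals, at least 10 min — by ``cv_multiple * assay_cv`` times that
    minimum.  The minimum of noisy samples is biased low, so the multiple is
    set conservatively; pulse amplitudes several-fold above basal leave a
    wide margin.
    """
    c = np.asarray(series.concentrations, float)
    t = np.asarray(series.times, float)
    if len(c) < 3:
        return np.asarray([]), np.asarray([])
    dt = float(np.median(np.diff(t)))
    lookback = max(2.0 * dt, 600.0)
    times, amps = [], []
    starts = np.searchsorted(t, t - lookback, side="left")
    for i in range(1, len(c) - 1):
        if starts[i] >= i:
            continue
        prev_min = float(np.min(c[starts[i] : i]))
        if (
            c[i] > c[i - 1]
            and c[i] >= c[i + 1]
            and c[i] >= prev_min * (1.0 + cv_multiple * assay_cv)
        ):
            times.append(t[i])
            amps.append(c[i])
    return np.asarray(times), np.asarray(amps)


def align_events(
    dse_peak_times: Sequence[float],
    lh_peak_times: Sequence[float],
    window_min: float = 20.0,
) -> AlignmentResult:
    """Match LH pulses to their generating dSEs.

    Each LH pulse is attributed to the latest unused dSE preceding it by no
    more than ``window_min`` minutes — when two dSEs fall close together
    their LH pulses merge, and the merged peak belongs to the later episode.
    Matching is greedy in time and order-preserving: each series item is used
    at most once and matched pairs never cross.
    """
    dse = np.sort(np.asarray(dse_peak_times, float))
    lh = np.sort(np.asarray(lh_peak_times, float))
    pairs: List[Tuple[float, float, float]] = []
    next_free = 0  # first unused dSE index
    for p in lh:
        cand = None
        for j in range(next_free, len(dse)):
            if dse[j] >= p:
                break
            if p - dse[j] <= 60.0 * window_min:
                cand = j
        if cand is not None:
            pairs.append((float(dse[cand]), float(p), (p - dse[cand]) / 60.0))
            next_free = cand + 1
    lags = np.asarray([q[2] for q in pairs])
    mean = float(np.mean(lags)) if len(lags) else None
    sem = float(np.std(lags, ddof=1) / np.sqrt(len(lags))) if len(lags) > 1 else None
    return AlignmentResult(
        pairs=pairs,
        mean_lag_min=mean,
        sem_lag_min=sem,
        unmatched_dse=len(dse) - len(pairs),
        unmatched_lh=len(lh) - len(pairs),
    )


def surge_concordance(
    ca_onset_s: Optional[float],
    ca_offset_s: Optional[float],
    lh: LHSeries,
) -> Dict[str, Optional[float]]:
    """Relate the LH surge to the slow calcium envelope.

    LH surge onset is where the series first exceeds twice the
    pre-(calcium-)onset median; return-to-basal is where it first falls back
    below basal + 10% of the LH excursion (mirroring the calcium offset
    rule), or below twice basal if that is higher.  Both crossings happen
    between samples of a sparse series, so they are placed at the midpoint
    of the bracketing sample pair (midpoint imputation for interval-censored
    times).  Reports the onset difference (LH − calcium, hours) and the
    offset difference (calcium − LH, hours; positive when calcium outlasts
    LH).
    """
    t = np.asarray(lh.times, float)
    c = np.asarray(lh.concentrations, float)
    report: Dict[str, Optional[float]] = {
        "lh_onset_s": None,
        "lh_peak_s": None,
        "lh_peak_ng_ml": None,
        "lh_return_s": None,
        "onset_diff_h": None,
        "offset_diff_h": None,
        "surge_absent": False,
    }
    if len(c) < 6:
        report["surge_absent"] = True
        return report
    pre = c[t < ca_onset_s] if ca_onset_s is not None else c[: max(2, len(c) // 4)]
    if len(pre) < 3:
        # too few samples before the calcium onset for a stable basal
        # estimate: take the lowest quartile of the whole series instead
        # (inter-pulse nadirs), which is robust to the surge and to pulses
        pre = np.sort(c)[: max(2, len(c) // 4)]
    basal = float(np.median(pre))
    thresh = 2.0 * basal
    above = np.nonzero(c > thresh)[0]
    if len(above) == 0:
        report["surge_absent"] = True
        return report
    i_on = int(above[0])
    i_pk = i_on + int(np.argmax(c[i_on:]))
    ret_level = max(thresh, basal + 0.10 * (float(c[i_pk]) - basal))
    after = np.nonzero(c[i_pk + 1 :] <= ret_level)[0]
    i_ret = i_pk + 1 + int(after[0]) if len(after) else None
    t_on = float(0.5 * (t[i_on - 1] + t[i_on])) if i_on > 0 else float(t[i_on])
    report["lh_onset_s"] = t_on
    report["lh_peak_s"] = float(t[i_pk])
    report["lh_peak_ng_ml"] = float(c[i_pk])
    if i_ret is not None:
        report["lh_return_s"] = float(0.5 * (t[i_ret - 1] + t[i_ret]))
    if ca_onset_s is not None:
        report["onset_diff_h"] = (t_on - ca_onset_s) / 3600.0
    if ca_offset_s is not None and i_ret is not None:
        report["offset_diff_h"] = (ca_offset_s - report["lh_return_s"]) / 3600.0
    return report


def normalized_overlay(
    dse_peak_times: Sequence[float],
    dff_time: np.ndarray,
    dff: np.ndarray,
    lh: LHSeries,
    window_min: Tuple[float, float] = (-20.0, 30.0),
    grid_step_s: float = 10.0,
) -> Dict[str, np.ndarray]:
    """Average min-max-normalized calcium and LH around each dSE peak.

    Returns a dict with keys ``offset_s``, ``calcium``, ``lh`` (each curve in
    [0, 1]); time 0 is the dSE peak.
    """
    lo, hi = (60.0 * w for w in window_min)
    grid = np.arange(lo, hi + grid_step_s / 2, grid_step_s)
    ca_stack, lh_stack = [], []
    for p in dse_peak_times:
        if p + lo < dff_time[0] or p + hi > dff_time[-1]:
            continue
        ca = np.interp(grid + p, dff_time, dff)
        lhv = np.interp(grid + p, lh.times, lh.concentrations)
        for seg, stack in ((ca, ca_stack), (lhv, lh_stack)):
            rng_ = seg.max() - seg.min()
            stack.append((seg - seg.min()) / rng_ if rng_ > 0 else np.zeros_like(seg))
    if not ca_stack:
        return {"offset_s": grid, "calcium": np.asarray([]), "lh": np.asarray([])}
    return {
        "offset_s": grid,
        "calcium": np.mean(ca_stack, axis=0),
        "lh": np.mean(lh_stack, axis=0),
    }
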