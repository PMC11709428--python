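"""Proestrus surge extraction: 30-min rolling average, onset/peak/offset
rules, incline/decline FWHM, and ultradian oscillation segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .smoothing import movmean_seconds
from .types import DffTrace


@dataclass
class SurgeDetectionParams:
    window_s: float = 1800.0  # 30-min rolling average
    onset_exceed_pp: float = 5.0  # above the pre-surge maximum
    offset_return_frac: float = 0.10  # elevation decayed by 90%
    baseline_window_s: float = 7200.0  # first 2 h
    trough_prominence_pp: float = 2.0
    trough_min_separation_s: float = 1200.0
    min_trace_s: float = 43200.0  # 12 h
    onset_mode: str = "baseline"  # or "running_max" (literal reading)


@dataclass
class SurgeProfile:
    surge_trace: np.ndarray  # smoothed dF/F %
    time: np.ndarray  # s
    onset_time: float
    peak_time: float
    offset_time: Optional[float]
    baseline_pp: float
    peak_amplitude: float  # dF/F % above baseline
    incline_fwhm_h: Optional[float]
    decline_fwhm_h: Optional[float]
    oscillations: List[Tuple[float, float, float]] = field(default_factory=list)
    # (trough_start_s, trough_end_s, duration_min)
    truncated: bool = False
    pulse_subtracted_input_flag: bool = False

    @property
    def onset_to_peak_h(self) -> float:
        return (self.peak_time - self.onset_time) / 3600.0

    @property
    def oscillation_durations_min(self) -> np.ndarray:
        return np.asarray([d for _, _, d in self.oscillations])


def rolling_average(dff: DffTrace, window_s: float = 1800.0) -> np.ndarray:
    """Centered moving mean; edges shrink to the available samples."""
    return movmean_seconds(dff.dff, window_s, dff.sampling_rate)


def excise_and_interpolate(
    dff: DffTrace,
    peak_times: Sequence[float],
    window_s: Tuple[float, float] = (60.0, 360.0),
) -> np.ndarray:
    """Replace each event window [-pre, +post] with linear interpolation.

    Used to feed the surge smoother a pulse-free trace so that episode bumps
    do not leak into the slow component.
    """
    t = np.asarray(dff.time)
    y = np.asarray(dff.dff, float).copy()
    pre, post = window_s
    excl = np.zeros(len(t), bool)
    for p in peak_times:
        excl |= (t >= p - pre) & (t <= p + post)
    if excl.any() and not excl.all():
        y[excl] = np.interp(t[excl], t[~excl], y[~excl])
    return y


def detect_surge(
    dff: DffTrace,
    params: Optional[SurgeDetectionParams] = None,
    smoothed: Optional[np.ndarray] = None,
    pulse_subtracted: bool = False,
) -> Optional[SurgeProfile]:
    """Locate a slow surge in the smoothed trace; None when no onset qualifies.

    Onset: earliest time the smoothed signal exceeds the pre-surge level by
    more than ``onset_exceed_pp``.  In the default ``baseline`` mode the
    pre-surge reference is the median of the baseline epoch (first
    ``baseline_window_s``); the literal ``running_max`` mode compares each
    sample to the running maximum of all earlier samples, which can only fire
    on a discontinuous rise and is kept for completeness.  Peak: the highest
    smoothed value after onset.  Offset: first time after the peak the signal
    falls back to baseline + ``offset_return_frac`` of the excursion (the
    elevation has decayed by 90%).  Incline/decline FWHM come from
    interpolated half-excursion crossings on either limb.
    """
    params = params or SurgeDetectionParams()
    t = np.asarray(dff.time)
    if t[-1] - t[0] < params.min_trace_s:
        raise ValueError("surge detection requires >= 12 h of data")
    y = smoothed if smoothed is not None else rolling_average(dff, params.window_s)
    y = np.asarray(y, float)

    base_sel = t <= t[0] + params.baseline_window_s
    if params.onset_mode == "running_max":
        runmax = np.maximum.accumulate(y)
        prev_max = np.concatenate([[y[0]], runmax[:-1]])
        exceed = y > prev_max + params.onset_exceed_pp
    else:
        ref = float(np.median(y[base_sel]))
        exceed = y > ref + params.onset_exceed_pp
        exceed[base_sel] = False
    if not exceed.any():
        return None
    i_on = int(np.argmax(exceed))
    i_pk = i_on + int(np.argmax(y[i_on:]))

    baseline = float(np.median(y[base_sel]))
    excursion = float(y[i_pk] - baseline)
    if excursion <= 0:
        return None

    ret_level = baseline + params.offset_return_frac * excursion
    after = np.nonzero(y[i_pk:] <= ret_level)[0]
    truncated = len(after) == 0
    i_off = None if truncated else i_pk + int(after[0])

    half = baseline + 0.5 * excursion
    incline = _last_up_crossing(t, y, half, i_on, i_pk)
    decline = None
    if not truncated:
        decline = _first_down_crossing(t, y, half, i_pk, i_off)

    profile = SurgeProfile(
        surge_trace=y,
        time=t,
        onset_time=float(t[i_on]),
        peak_time=float(t[i_pk]),
        offset_time=float(t[i_off]) if i_off is not None else None,
        baseline_pp=baseline,
        peak_amplitude=excursion,
        incline_fwhm_h=(t[i_pk] - incline) / 3600.0 if incline is not None else None,
        decline_fwhm_h=(decline - t[i_pk]) / 3600.0 if decline is not None else None,
        truncated=truncated,
        pulse_subtracted_input_flag=pulse_subtracted,
    )
    end = profile.offset_time if profile.offset_time is not None else float(t[-1])
    profile.oscillations = segment_oscillations(
        t, y, profile.onset_time, end, dff.sampling_rate, params
    )
    return profile


def _last_up_crossing(t, y, level, i0, i1):
    idx = np.nonzero((y[i0:i1] <= level) & (y[i0 + 1 : i1 + 1] > level))[0]
    if len(idx) == 0:
        return None
    i = i0 + int(idx[-1])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _first_down_crossing(t, y, level, i0, i1):
    idx = np.nonzero((y[i0:i1] >= level) & (y[i0 + 1 : i1 + 1] < level))[0]
    if len(idx) == 0:
        return None
    i = i0 + int(idx[0])
    frac = (y[i] - level) / (y[i] - y[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def segment_oscillations(
    time: np.ndarray,
    smoothed: np.ndarray,
    onset_s: float,
    offset_s: float,
    sampling_rate: float,
    params: Optional[SurgeDetectionParams] = None,
) -> List[Tuple[float, float, float]]:
    """Trough-to-trough segmentation of the slow oscillations.

    Troughs are local minima of the smoothed trace between onset and offset
    with the configured prominence and separation; each consecutive trough
    pair defines one oscillation whose duration is reported in minutes.
    """
    params = params or SurgeDetectionParams()
    sel = (time >= onset_s) & (time <= offset_s)
    if sel.sum() < 3:
        return []
    y = smoothed[sel]
    t = time[sel]
    idx, _ = find_peaks(
        -y,
        prominence=params.trough_prominence_pp,
        distance=max(1, int(params.trough_min_separation_s * sampling_rate)),
    )
    if len(idx) < 2:
        return []
    troughs = t[idx]
    return [
        (float(a), float(b), float((b - a) / 60.0))
        for a, b in zip(troughs[:-1], troughs[1:])
    ]


def subtract_surge(dff: DffTrace, surge_trace: np.ndarray) -> DffTrace:
    """Pointwise residual: the pulse-and-baseline trace left after the surge."""
    if len(surge_trace) != len(dff.dff):
        raise ValueError("surge trace and dff are on different grids")
    return DffTrace(
        time=dff.time,
        dff=dff.dff - np.asarray(surge_trace, float),
        sampling_rate=dff.sampling_rate,
        baseline_fit=dff.baseline_fit,
        reference_fit=dff.reference_fit,
        provenance=dict(dff.provenance, surge_subtracted=True),
        metadata=dict(dff.metadata),
    )
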