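"""Synthetic two-channel photometry and coupled LH series.

The generator composes, on a common 10 Hz grid, the three oscillatory modes of
GnRH dendron activity — abrupt dendron synchronization episodes (dSEs) with
right-skewed inter-event intervals, low-amplitude clustered baseline
micro-activity, and (on proestrus) a slow surge envelope carrying ~78-min
ultradian oscillations — plus photobleaching, shared motion artifacts and
sensor noise, and renders LH secretion as basal + dSE-locked pulses + a
desensitizing surge response.  Every rendered component is logged in a
:class:`GroundTruth` so each analysis stage can be validated by parameter
recovery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, fsolve

from .config import ConfigurationError, DseShape, SimConfig
from .lh import LHSeries
from .smoothing import movmean
from .types import RawPhotometry

_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


# ----------------------------------------------------------------------
# Ground truth bookkeeping
# ----------------------------------------------------------------------
@dataclass
class GroundTruth:
    """Record of every component rendered into a synthetic trace."""

    dse_peak_times: np.ndarray  # s
    dse_amplitudes: np.ndarray  # dF/F %
    cluster_intervals: List[Tuple[float, float]]  # s
    baseline_event_times: np.ndarray  # s
    surge_envelope: Optional[np.ndarray]  # dF/F % on the trace grid
    oscillation_trough_times: np.ndarray  # s
    lh_pulse_peak_times: np.ndarray  # s
    bleach_curve: np.ndarray  # a.u., 465 channel
    surge_info: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.dse_peak_times, float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("dse_peak_times must be strictly increasing")

    def to_json(self, path, time: Optional[np.ndarray] = None) -> None:
        """Write the event-level ground truth as a JSON sidecar.

        The full-resolution envelope/bleach arrays are summarised on a 1-min
        grid to keep the sidecar small.
        """
        out = {
            "dse_peak_times_s": list(map(float, self.dse_peak_times)),
            "dse_amplitudes_pct": list(map(float, self.dse_amplitudes)),
            "cluster_intervals_s": [[float(a), float(b)] for a, b in self.cluster_intervals],
            "baseline_event_times_s": list(map(float, self.baseline_event_times)),
            "oscillation_trough_times_s": list(map(float, self.oscillation_trough_times)),
            "lh_pulse_peak_times_s": list(map(float, self.lh_pulse_peak_times)),
            "surge_info": {k: float(v) for k, v in self.surge_info.items()},
        }
        if self.surge_envelope is not None and time is not None:
            step = max(1, int(round(60.0 * len(time) / (time[-1] - time[0] + 1e-9))))
            out["surge_envelope_1min_pct"] = list(map(float, self.surge_envelope[::step]))
        with open(path, "w") as fh:
            json.dump(out, fh)


# ----------------------------------------------------------------------
# dSE waveform
# ----------------------------------------------------------------------
@lru_cache(maxsize=64)
def _calibrate_decay(
    rise_fwhm_s: float, decay_fwhm_s: float, total_duration_s: float, tail_fraction: float
) -> Tuple[float, float, float]:
    """Solve the decay time constants of the skewed kernel.

    Returns (sigma_rise, tau_fast, tau_slow) such that the half-Gaussian rise
    has a half-max-to-peak width of ``rise_fwhm_s`` and the two-exponential
    decay crosses 0.5 at ``decay_fwhm_s`` and 0.05 at the offset implied by
    ``total_duration_s``.
    """
    sigma = rise_fwhm_s / _SQRT_2LN2
    rise5 = sigma * math.sqrt(2.0 * math.log(20.0))  # 5% crossing before peak
    t5 = total_duration_s - rise5
    w = decay_fwhm_s
    f = tail_fraction
    if t5 <= w:
        raise ConfigurationError(
            "infeasible dse shape: total duration leaves no room beyond the decay FWHM"
        )

    def eqs(logtaus):
        tf, ts = np.exp(logtaus)
        return [
            (1 - f) * math.exp(-w / tf) + f * math.exp(-w / ts) - 0.5,
            (1 - f) * math.exp(-t5 / tf) + f * math.exp(-t5 / ts) - 0.05,
        ]

    # slow tail must still hold 0.05 of the peak at t5
    ts0 = t5 / math.log(max(f / 0.05, 1.001))
    tf0 = w / math.log(2.0)
    sol, info, ier, _ = fsolve(eqs, np.log([tf0, max(ts0, tf0 * 1.5)]), full_output=True)
    tf, ts = np.exp(sol)
    if ier != 1 or not (0 < tf < ts) or max(abs(r) for r in eqs(sol)) > 1e-9:
        raise ConfigurationError(
            "infeasible dse shape: no two-exponential decay matches "
            f"FWHM={w}s and 5%-crossing at {t5:.1f}s with tail fraction {f}"
        )
    return sigma, tf, ts


def render_dse_kernel(shape: DseShape, t_grid: np.ndarray) -> np.ndarray:
    """Unit-amplitude dSE waveform on ``t_grid`` (seconds, peak at t=0)."""
    t = np.asarray(t_grid, float)
    if shape.kind == "gaussian":
        return np.exp(-(t**2) / (2.0 * shape.sigma_s**2))
    sigma, tf, ts = _calibrate_decay(
        shape.rise_fwhm_s, shape.decay_fwhm_s, shape.total_duration_s, shape.tail_fraction
    )
    out = np.empty_like(t)
    rise = t <= 0
    out[rise] = np.exp(-(t[rise] ** 2) / (2.0 * sigma**2))
    f = shape.tail_fraction
    out[~rise] = (1 - f) * np.exp(-t[~rise] / tf) + f * np.exp(-t[~rise] / ts)
    return out


def kernel_support(shape: DseShape, cutoff: float = 1e-3) -> Tuple[float, float]:
    """(pre, post) extent in seconds at which the kernel falls below ``cutoff``."""
    if shape.kind == "gaussian":
        half = shape.sigma_s * math.sqrt(2.0 * math.log(1.0 / cutoff))
        return half, half
    sigma, tf, ts = _calibrate_decay(
        shape.rise_fwhm_s, shape.decay_fwhm_s, shape.total_duration_s, shape.tail_fraction
    )
    pre = sigma * math.sqrt(2.0 * math.log(1.0 / cutoff))
    post = ts * math.log(max(shape.tail_fraction, cutoff * 2) / cutoff)
    return pre, post


# ----------------------------------------------------------------------
# Inter-dSE intervals
# ----------------------------------------------------------------------
def draw_intervals(
    config: SimConfig, n: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw ``n`` inter-dSE intervals (seconds) from the profile distribution.

    Gamma family with shape pinned to the stage skewness; values outside the
    configured truncation range are resampled.
    """
    dist = config.interval_dist
    dist.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x1D)))
    scale = dist.mean_min / dist.shape
    lo, hi = dist.trunc_min
    out = rng.gamma(dist.shape, scale, size=n)
    for _ in range(200):
        bad = np.zeros(n, bool)
        if lo is not None:
            bad |= out < lo
        if hi is not None:
            bad |= out > hi
        if not bad.any():
            break
        out[bad] = rng.gamma(dist.shape, scale, size=int(bad.sum()))
    return out * 60.0


# ----------------------------------------------------------------------
# Baseline clusters
# ----------------------------------------------------------------------
def render_baseline_clusters(
    config: SimConfig,
    duration_s: float,
    t_grid: np.ndarray,
    dse_peak_times: Sequence[float] = (),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, List[Tuple[float, float]], np.ndarray]:
    """Render clustered micro-activity; returns (series_pct, intervals, event_times).

    Clusters are placed clear of each dSE footprint [peak-120 s, peak+660 s]:
    during an episode the micro-activity is swamped by the episode itself.
    Inter-cluster gaps are drawn >= 8 min so the downstream 420 s separation
    rule can resolve cluster boundaries.
    """
    bc = config.baseline_cluster
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x2D)))
    series = np.zeros_like(t_grid)
    amp = bc.rel_amplitude_frac_of_dse * config.dse_shape.amplitude_dff_pct
    intervals: List[Tuple[float, float]] = []
    event_times: List[float] = []
    if amp <= 0:
        return series, intervals, np.asarray(event_times)

    forbidden = sorted((p - 120.0, p + 660.0) for p in dse_peak_times)
    gap_lo, gap_hi = (60.0 * g for g in bc.inter_cluster_gap_min_range)
    mean_dur = 60.0 * bc.mean_cluster_duration_min
    shape_d = bc.duration_gamma_shape
    spacing = 1.0 / bc.intra_cluster_freq_hz
    dt = t_grid[1] - t_grid[0] if len(t_grid) > 1 else 0.1
    half_w = bc.event_width_s / 2.0

    t = rng.uniform(0.0, gap_hi)
    while t < duration_s:
        dur = rng.gamma(shape_d, mean_dur / shape_d)
        s, e = t, t + dur
        for _ in range(100):  # slide past dSE footprints
            hit = next((fe for fs, fe in forbidden if s < fe and e > fs), None)
            if hit is None:
                break
            s = hit + rng.uniform(60.0, 180.0)
            e = s + dur
        if e > duration_s:
            break
        intervals.append((s, e))
        n_ev = max(1, int(math.floor(dur / spacing)))
        times = s + spacing / 2.0 + spacing * np.arange(n_ev)
        times = times + rng.normal(0.0, bc.event_jitter_s, size=n_ev)
        times = np.clip(times, s + 1.0, e - 1.0)
        times.sort()
        for tc in times:
            a = amp * (1.0 + bc.amplitude_jitter_frac * rng.standard_normal())
            a = max(a, 0.3 * amp)
            i0 = max(0, int((tc - half_w) / dt))
            i1 = min(len(t_grid), int((tc + half_w) / dt) + 2)
            dt_loc = t_grid[i0:i1] - tc
            bump = np.where(
                np.abs(dt_loc) < half_w,
                0.5 * (1.0 + np.cos(np.pi * dt_loc / half_w)),
                0.0,
            )
            series[i0:i1] += a * bump
        event_times.extend(times)
        t = e + rng.uniform(gap_lo, gap_hi)
    return series, intervals, np.asarray(event_times)


# ----------------------------------------------------------------------
# Proestrus surge envelope
# ----------------------------------------------------------------------
def render_surge_envelope(
    config: SimConfig,
    t_grid: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Render the slow surge component (dF/F %) and its oscillation troughs.

    The envelope's rising and falling limbs are monotone PCHIP curves through
    the configured anchors.  The nominal onset is defined consistently with
    the downstream 5-pp detection rule: the clean envelope crosses
    ``onset_detect_pp`` exactly at the onset time, with a sub-detection foot
    of ``foot_h`` hours before it.  A multiplicative oscillation with
    trough-to-trough periods drawn around ``osc_period_min`` (clipped to the
    configured range) rides on the envelope.
    """
    sp = config.surge
    if sp is None:
        raise ConfigurationError("profile has no surge parameters")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x3D)))

    amp = rng.uniform(*sp.peak_dff_pct)
    onset = (
        config.lights_off_s
        - 3600.0 * sp.onset_h_before_lights_off
        + 3600.0 * sp.onset_jitter_h * rng.standard_normal()
    )
    truncated = onset - 3600.0 * sp.foot_h < t_grid[0]
    onset = max(onset, t_grid[0] + 3600.0 * sp.foot_h)
    peak = onset + 3600.0 * sp.onset_to_peak_h
    offset = onset + 3600.0 * sp.onset_to_offset_h
    t0 = onset - 3600.0 * sp.foot_h
    tail_end = offset + 1800.0

    rise = PchipInterpolator(
        [t0, onset, peak - 3600.0 * sp.incline_fwhm_h, peak],
        [0.0, sp.onset_detect_pp / amp, 0.5, 1.0],
    )
    fall = PchipInterpolator(
        [peak, peak + 3600.0 * sp.decline_fwhm_h, offset, tail_end],
        [1.0, 0.5, 0.03, 0.0],
    )
    env = np.zeros_like(t_grid)
    m_rise = (t_grid >= t0) & (t_grid <= peak)
    m_fall = (t_grid > peak) & (t_grid <= tail_end)
    env[m_rise] = rise(t_grid[m_rise])
    env[m_fall] = fall(t_grid[m_fall])
    env = amp * np.clip(env, 0.0, 1.0)

    # oscillation: piecewise-linear phase; troughs at multiples of 2*pi
    lo, hi = sp.osc_period_range_min
    phase0 = rng.uniform(0.0, 2.0 * math.pi)
    p_first = float(np.clip(rng.normal(sp.osc_period_min, sp.osc_period_sd_min), lo, hi))
    nodes = [t0 - 60.0 * p_first * phase0 / (2.0 * math.pi)]
    while nodes[-1] < tail_end:
        p = float(np.clip(rng.normal(sp.osc_period_min, sp.osc_period_sd_min), lo, hi))
        nodes.append(nodes[-1] + 60.0 * p)
    nodes_arr = np.asarray(nodes)
    phase = np.interp(t_grid, nodes_arr, 2.0 * math.pi * np.arange(len(nodes_arr)))
    # zero-mean modulation around the envelope: troughs at the phase nodes
    factor = 1.0 - 0.5 * sp.osc_mod_depth * np.cos(phase)
    if sp.osc_mod_depth == 0:
        troughs = np.asarray([])
    else:
        troughs = nodes_arr[(nodes_arr > onset) & (nodes_arr < offset)]

    info = {
        "onset_s": onset,
        "peak_s": peak,
        "offset_s": offset,
        "amplitude_pct": amp,
        "truncated": float(truncated),
    }
    return env * factor, troughs, info


# ----------------------------------------------------------------------
# Trace assembly
# ----------------------------------------------------------------------
def assemble_trace(config: SimConfig, return_components: bool = False):
    """Render a full synthetic recording.

    Returns ``(RawPhotometry, GroundTruth)``; with ``return_components=True``
    a third dict carries the noiseless additive components (dF/F %) so that
    component additivity can be verified.
    """
    config.validate()
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    children = np.random.SeedSequence(config.seed).spawn(7)
    rng_int, rng_amp, rng_clu, rng_sur, rng_mot, rng_n465, rng_n405 = (
        np.random.default_rng(s) for s in children
    )

    # surge first: its peak gates dSE suppression
    surge_pp = np.zeros(n)
    troughs = np.asarray([])
    surge_info: Dict[str, float] = {}
    if config.surge is not None:
        surge_pp, troughs, surge_info = render_surge_envelope(config, t, rng_sur)

    # dSE peak times from the interval distribution
    amp0 = config.dse_shape.amplitude_dff_pct
    peaks: List[float] = []
    if amp0 > 0:
        margin = 120.0
        est = max(4, int(2.5 * config.duration_s / (60.0 * config.interval_dist.mean_min)))
        gaps = draw_intervals(config, est, rng_int)
        cum = np.cumsum(gaps)
        while cum[-1] < config.duration_s:
            gaps = np.concatenate([gaps, draw_intervals(config, est, rng_int)])
            cum = np.cumsum(gaps)
        peaks = [float(c) for c in cum if c < config.duration_s - margin]
        if config.surge is not None and config.surge.dse_suppression_h > 0 and surge_info:
            p0 = surge_info["peak_s"]
            p1 = p0 + 3600.0 * config.surge.dse_suppression_h
            peaks = [p for p in peaks if not (p0 <= p <= p1)]
    peaks_arr = np.asarray(peaks)

    amps = np.asarray([])
    dse_pp = np.zeros(n)
    if len(peaks_arr):
        jit = config.dse_shape.amplitude_jitter_frac
        amps = amp0 * (1.0 + jit * rng_amp.standard_normal(len(peaks_arr)))
        amps = np.maximum(amps, 0.3 * amp0)
        pre, post = kernel_support(config.dse_shape)
        off = np.arange(-int(pre / dt), int(post / dt) + 1) * dt
        kern = render_dse_kernel(config.dse_shape, off)
        for p, a in zip(peaks_arr, amps):
            i0 = int(round(p / dt)) - int(pre / dt)
            j0, j1 = max(i0, 0), min(i0 + len(kern), n)
            dse_pp[j0:j1] += a * kern[j0 - i0 : j1 - i0]

    cluster_pp, cluster_intervals, base_events = render_baseline_clusters(
        config, config.duration_s, t, peaks_arr, rng_clu
    )

    comp = (dse_pp + cluster_pp + surge_pp) / 100.0

    bl = config.bleach
    bleach465 = bl.f0 * ((1 - bl.depth_frac) + bl.depth_frac * np.exp(-t / bl.tau_s))
    bleach405 = (
        bl.f0
        * bl.ref_level_frac
        * ((1 - bl.depth_frac) + bl.depth_frac * np.exp(-t / (bl.tau_s * bl.ref_tau_factor)))
    )

    nz = config.noise
    # motion artifacts are fractional losses/gains of collected light and so
    # scale with each channel's fluorescence; the reference regression can
    # then cancel them
    motion = np.zeros(n)
    n_art = rng_mot.poisson(nz.motion_artifact_rate_per_h * config.duration_s / 3600.0)
    if n_art and nz.motion_artifact_amp_frac > 0:
        sd = nz.motion_artifact_width_s / 2.0
        for tc in rng_mot.uniform(0, config.duration_s, n_art):
            i0 = max(0, int((tc - 4 * sd) / dt))
            i1 = min(n, int((tc + 4 * sd) / dt) + 1)
            d = t[i0:i1] - tc
            motion[i0:i1] += (
                nz.motion_artifact_amp_frac * (d / sd) * np.exp(0.5 - d**2 / (2 * sd**2))
            )

    f465 = bleach465 * (1.0 + comp + motion)
    f405 = bleach405 * (1.0 + motion)
    if nz.sensor_sd > 0:
        f465 = f465 + (nz.sensor_sd / 100.0) * bl.f0 * rng_n465.standard_normal(n)
        f405 = f405 + (nz.sensor_sd / 100.0) * bl.f0 * bl.ref_level_frac * rng_n405.standard_normal(n)
    f465 = np.maximum(f465, 0.0)
    f405 = np.maximum(f405, 0.0)

    if config.acquisition.mode == "scheduled":
        cyc = config.acquisition.on_s + config.acquisition.off_s
        mask = ((t % cyc) < config.acquisition.on_s).astype(np.uint8)
        f465 = f465 * mask
        f405 = f405 * mask
    else:
        mask = np.ones(n, np.uint8)

    raw = RawPhotometry(
        time=t,
        f465=f465,
        f405=f405,
        mask=mask,
        sampling_rate=fs,
        metadata={
            "profile": config.profile_name,
            "lights_on": config.lights_on,
            "lights_off": config.lights_off,
            "start_clock": config.start_clock,
            "acquisition": config.acquisition.mode,
        },
    )
    gt = GroundTruth(
        dse_peak_times=peaks_arr,
        dse_amplitudes=amps,
        cluster_intervals=cluster_intervals,
        baseline_event_times=base_events,
        surge_envelope=surge_pp if config.surge is not None else None,
        oscillation_trough_times=troughs,
        lh_pulse_peak_times=peaks_arr + 60.0 * config.lh.peak_lag_min
        if len(peaks_arr)
        else np.asarray([]),
        bleach_curve=bleach465,
        surge_info=surge_info,
    )
    if return_components:
        comps = {"dse": dse_pp, "baseline": cluster_pp, "surge": surge_pp}
        return raw, gt, comps
    return raw, gt


# ----------------------------------------------------------------------
# LH secretion
# ----------------------------------------------------------------------
def _pulse_rise_tau(tau_d: float, lag_s: float) -> float:
    """Rise constant of the difference-of-exponentials pulse peaking at lag_s."""

    def peak_time(tr):
        return math.log(tau_d / tr) * tr * tau_d / (tau_d - tr) - lag_s

    return brentq(peak_time, 1e-3, tau_d * 0.999)


def simulate_lh(
    gt: GroundTruth,
    config: SimConfig,
    sampling_times: Sequence[float],
    noiseless: bool = False,
) -> LHSeries:
    """Sample the latent LH concentration at ``sampling_times`` (seconds).

    Latent LH = basal + a difference-of-exponentials pulse per dSE (peaking
    ``peak_lag_min`` after the dSE peak, clearing with the configured
    half-life) + a surge term driven by the slow calcium envelope through a
    desensitizing gain that shuts off once cumulative exposure passes the
    level reached at the envelope peak.  Samples carry lognormal assay noise
    (CV ``assay_cv``) and are floored at the assay sensitivity.
    """
    st = np.asarray(sampling_times, float)
    lp = config.lh
    if len(st) == 0:
        return LHSeries(times=st, concentrations=np.asarray([]), sampling_interval=0.0)

    tau_d = 60.0 * lp.clearance_halflife_min / math.log(2.0)
    lag_s = 60.0 * lp.peak_lag_min
    tau_r = _pulse_rise_tau(tau_d, lag_s)
    norm = 1.0 / (
        math.exp(-lag_s / tau_d) - math.exp(-lag_s / tau_r)
    )

    latent = np.full(len(st), lp.basal_ng_ml)

    # pituitary desensitization: a sigmoidal gain in cumulative normalized
    # calcium exposure, shutting off shortly after the envelope peak; it
    # blunts both the surge response and post-surge pulses
    gain_at = None
    if gt.surge_envelope is not None and np.max(gt.surge_envelope) > 0:
        n_env = len(gt.surge_envelope)
        t_env = np.arange(n_env) / config.sampling_rate
        step = max(1, int(config.sampling_rate * 10))  # 10 s grid is ample
        te, env = t_env[::step], gt.surge_envelope[::step]
        # the LH surge is driven by the slow envelope, not by the ~78-min
        # ultradian crests riding on it: a 90-min moving mean suppresses the
        # oscillation from the drive while leaving the hours-scale envelope
        env = movmean(env, max(1, int(5400.0 / (te[1] - te[0]))))
        env_n = env / np.max(env)
        expo = np.concatenate([[0.0], cumulative_trapezoid(env_n, te / 3600.0)])
        i_peak = int(np.argmax(env_n))
        w = max(lp.surge_desensitization_h, 1e-6)
        midpoint = expo[i_peak] + lp.surge_desens_delay_h
        gain = 1.0 / (1.0 + np.exp((expo - midpoint) / w))
        gain_at = lambda x: np.interp(x, te, gain, left=1.0, right=float(gain[-1]))
        prof = env_n * gain
        scale = (lp.surge_peak_ng_ml - lp.basal_ng_ml) / np.max(prof)
        latent += np.interp(st, te, scale * prof, left=0.0, right=0.0)

    for p in np.asarray(gt.dse_peak_times, float):
        d = st - p
        m = d > 0
        g = float(gain_at(p)) if gain_at is not None else 1.0
        latent[m] += (
            g * lp.pulse_amp_ng_ml * norm * (np.exp(-d[m] / tau_d) - np.exp(-d[m] / tau_r))
        )

    if not noiseless and lp.assay_cv > 0:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x4C48)))
        sig = math.sqrt(math.log(1.0 + lp.assay_cv**2))
        latent = latent * np.exp(rng.normal(-0.5 * sig**2, sig, size=len(st)))
    latent = np.maximum(latent, lp.assay_sensitivity_ng_ml)
    interval = float(np.median(np.diff(st))) if len(st) > 1 else 0.0
    return LHSeries(times=st, concentrations=latent, sampling_interval=interval)
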