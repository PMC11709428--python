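"""End-to-end orchestration: simulate → preprocess → deconvolve → detect →
residual → LH alignment, with a manifest recording every stage.

Stage order on proestrus follows the deconvolution logic: the slow surge is
extracted (from a pulse-excised copy of the trace) and subtracted before the
final dSE detection, so the three deconvolved traces — surge, pulse windows,
residual — sum back to the preprocessed ΔF/F sample-exactly.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .config import SimConfig, default_config
from .events import DetectionParams, EventSeries, detect_dse, interval_statistics
from .lh import align_events, detect_lh_pulses, surge_concordance
from .preprocess import preprocess
from .residual import (
    ResidualParams,
    cluster_and_score,
    excise_dse_windows,
    extract_residual_peaks,
    summarize_clusters,
)
from .simulate import assemble_trace, simulate_lh
from .smoothing import movmean_seconds
from .surge import (
    SurgeDetectionParams,
    detect_surge,
    excise_and_interpolate,
    subtract_surge,
)
from . import io as dsio


@dataclass
class AnalysisParams:
    """Analysis-side settings used by the pipeline."""

    reference_mode: str = "scaled"
    detection: DetectionParams = field(default_factory=DetectionParams)
    surge: SurgeDetectionParams = field(default_factory=SurgeDetectionParams)
    residual: ResidualParams = field(default_factory=lambda: ResidualParams(threshold_pp=1.0))
    lh_sampling_interval_s: float = 300.0
    lh_span_s: Optional[float] = None  # default: whole trace
    prepass_highpass_s: float = 600.0  # high-pass window for the surge pre-pass


@dataclass
class PipelineResult:
    """In-memory results of one run (the manifest references the files)."""

    config: SimConfig
    dff: object
    events: EventSeries
    surge_profile: object
    clusters: list
    cluster_summary: dict
    lh_series: object
    alignment: object
    concordance: Optional[dict]
    manifest: dict


def run_pipeline(
    config: SimConfig,
    outdir: Optional[Path] = None,
    params: Optional[AnalysisParams] = None,
    with_lh: bool = True,
) -> PipelineResult:
    """Run the full chain on a synthetic recording defined by ``config``."""
    params = params or AnalysisParams()
    manifest: Dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "profile": config.profile_name,
        "config": config.to_dict(),
        "stages": {},
        "outputs": [],
    }
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        manifest["stages"][name] = {"t_start": _time.monotonic()}

    def _done(name):
        st = manifest["stages"][name]
        st["wall_s"] = _time.monotonic() - st.pop("t_start")
        st["completed"] = True

    _stage("simulate")
    raw, gt = assemble_trace(config)
    _done("simulate")

    _stage("preprocess")
    dff = preprocess(raw, mode=params.reference_mode)
    _done("preprocess")

    surge_profile = None
    dff_for_events = dff
    if config.profile_name == "proestrus_surge":
        _stage("surge")
        # pre-pass: find pulse peaks on a high-passed copy, excise them, then
        # smooth; keeps episode bumps out of the running max the onset rule uses
        hp = dff.dff - movmean_seconds(dff.dff, params.prepass_highpass_s, dff.sampling_rate)
        from .types import DffTrace

        pre_events = detect_dse(
            DffTrace(time=dff.time, dff=hp, sampling_rate=dff.sampling_rate),
            params.detection,
        )
        clean = excise_and_interpolate(dff, pre_events.peak_times)
        smoothed = movmean_seconds(clean, params.surge.window_s, dff.sampling_rate)
        surge_profile = detect_surge(dff, params.surge, smoothed=smoothed, pulse_subtracted=True)
        if surge_profile is not None:
            dff_for_events = subtract_surge(dff, surge_profile.surge_trace)
        _done("surge")

    _stage("detect")
    events = detect_dse(dff_for_events, params.detection, stage=config.profile_name)
    _done("detect")

    _stage("residual")
    excl = excise_dse_windows(dff_for_events.time, events.peak_times)
    pk_t, pk_a = extract_residual_peaks(
        dff_for_events.time,
        dff_for_events.dff,
        excl,
        params.residual,
        dff_for_events.sampling_rate,
    )
    clusters = cluster_and_score(pk_t, pk_a, params.residual.cluster_gap_s)
    cluster_summary = summarize_clusters(clusters)
    _done("residual")

    lh_series = None
    alignment = None
    concordance = None
    if with_lh:
        _stage("lh")
        span = params.lh_span_s or config.duration_s
        times = np.arange(
            params.lh_sampling_interval_s, span + 1e-9, params.lh_sampling_interval_s
        )
        lh_series = simulate_lh(gt, config, times)
        lh_peaks, _amps = detect_lh_pulses(lh_series, assay_cv=config.lh.assay_cv)
        alignment = align_events(events.peak_times, lh_peaks)
        if surge_profile is not None:
            concordance = surge_concordance(
                surge_profile.onset_time, surge_profile.offset_time, lh_series
            )
        _done("lh")

    if outdir is not None:
        dsio.write_trace(outdir / "trace.tsv", raw)
        gt.to_json(outdir / "ground_truth.json", time=raw.time)
        dsio.write_dff(outdir / "dff.tsv", dff)
        dsio.write_events(outdir / "events.tsv", events)
        stats = interval_statistics(events.intervals_min)
        dsio.write_json(outdir / "interval_stats.json", _stats_dict(stats))
        dsio.write_clusters(outdir / "clusters.tsv", clusters)
        dsio.write_json(outdir / "cluster_summary.json", cluster_summary)
        if surge_profile is not None:
            dsio.write_json(outdir / "surge.json", _surge_dict(surge_profile, config))
        if lh_series is not None:
            dsio.write_lh(outdir / "lh.tsv", lh_series)
            dsio.write_json(outdir / "align.json", _alignment_dict(alignment, concordance))
        manifest["outputs"] = sorted(p.name for p in outdir.iterdir()) + ["manifest.json"]
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        config=config,
        dff=dff,
        events=events,
        surge_profile=surge_profile,
        clusters=clusters,
        cluster_summary=cluster_summary,
        lh_series=lh_series,
        alignment=alignment,
        concordance=concordance,
        manifest=manifest,
    )


def _stats_dict(stats) -> dict:
    d = {
        "n": stats.n,
        "mean_min": stats.mean_min,
        "sem_min": stats.sem_min,
        "skewness": stats.skewness,
        "kurtosis_pearson": stats.kurtosis_pearson,
        "kurtosis_excess": stats.kurtosis_excess,
        "shapiro_w": stats.shapiro_w,
        "shapiro_p": stats.shapiro_p,
        "histogram_bins_min": list(map(float, stats.histogram_bins_min)),
        "histogram_pct": list(map(float, stats.histogram_pct)),
    }
    return d


def _surge_dict(sp, config: SimConfig) -> dict:
    def clock(t_s):
        if t_s is None:
            return None
        start = config._clock_to_s(config.start_clock)
        s = (start + t_s) % 86400.0
        return f"{int(s // 3600):02d}:{int(s % 3600 // 60):02d}"

    return {
        "onset_s": sp.onset_time,
        "peak_s": sp.peak_time,
        "offset_s": sp.offset_time,
        "onset_clock": clock(sp.onset_time),
        "peak_clock": clock(sp.peak_time),
        "offset_clock": clock(sp.offset_time),
        "onset_to_peak_h": sp.onset_to_peak_h,
        "peak_amplitude_pp": sp.peak_amplitude,
        "incline_fwhm_h": sp.incline_fwhm_h,
        "decline_fwhm_h": sp.decline_fwhm_h,
        "n_oscillations": len(sp.oscillations),
        "mean_oscillation_min": float(np.mean(sp.oscillation_durations_min))
        if len(sp.oscillations)
        else None,
        "truncated": sp.truncated,
        "pulse_subtracted_input": sp.pulse_subtracted_input_flag,
    }


def _alignment_dict(al, concordance) -> dict:
    d = {
        "pairs": [list(p) for p in al.pairs],
        "mean_lag_min": al.mean_lag_min,
        "sem_lag_min": al.sem_lag_min,
        "unmatched_dse": al.unmatched_dse,
        "unmatched_lh": al.unmatched_lh,
    }
    if concordance is not None:
        d["surge_concordance"] = concordance
    return d


def report(result: PipelineResult) -> str:
    """Human-readable run summary."""
    lines = [
        f"dendrosync {__version__} — profile {result.config.profile_name}, "
        f"seed {result.config.seed}, {result.config.duration_s / 3600:.1f} h",
        f"events: {len(result.events)}",
    ]
    iv = result.events.intervals_min
    if len(iv):
        st = interval_statistics(iv)
        lines.append(
            f"mean inter-dSE interval: {st.mean_min:.1f} min (n={st.n}, skewness "
            f"{st.skewness:.2f})" if st.skewness is not None
            else f"mean inter-dSE interval: {st.mean_min:.1f} min (n={st.n})"
        )
    durs = [e.duration for e in result.events.events if e.duration is not None]
    if durs:
        lines.append(f"mean event duration: {float(np.mean(durs)):.0f} s")
    if result.events and not len(result.events):
        lines.append("zero events detected")
    if len(result.events) == 0:
        lines.append("zero events detected")
    sp = result.surge_profile
    if sp is not None:
        lines.append(
            f"surge: onset-to-peak {sp.onset_to_peak_h:.1f} h, amplitude "
            f"{sp.peak_amplitude:.1f} dF/F%, {len(sp.oscillations)} oscillations"
        )
    elif result.config.profile_name == "proestrus_surge":
        lines.append("surge: none detected")
    cs = result.cluster_summary
    if cs.get("mean_duration_min") is not None:
        lines.append(
            f"baseline clusters: {cs['n_clusters']} "
            f"(mean duration {cs['mean_duration_min']:.1f} min, "
            f"intra-cluster frequency {cs['mean_intra_cluster_freq_hz']:.4f} Hz)"
        )
    al = result.alignment
    if al is not None and al.mean_lag_min is not None:
        lines.append(
            f"dSE→LH lag: {al.mean_lag_min:.1f} min over {len(al.pairs)} pairs"
        )
    return "\n".join(lines)


def save_figures(result: PipelineResult, outdir: Path) -> List[Path]:
    """Write overview figures: the ΔF/F trace with detected events, and (on
    proestrus) the surge decomposition.  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    fig, ax = plt.subplots(figsize=(10, 3))
    t_h = result.dff.time / 3600.0
    ax.plot(t_h, result.dff.dff, lw=0.3, color="k")
    pk = result.events.peak_times
    if len(pk):
        amps = [e.peak_amplitude + e.local_baseline for e in result.events.events]
        ax.plot(pk / 3600.0, amps, "v", color="crimson", ms=4, label="dSE")
        ax.legend(frameon=False)
    ax.set(xlabel="time (h)", ylabel="ΔF/F (%)",
           title=f"{result.config.profile_name}, seed {result.config.seed}")
    fig.tight_layout()
    path = outdir / "trace_events.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if result.surge_profile is not None:
        sp = result.surge_profile
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.plot(t_h, result.dff.dff, lw=0.3, color="0.7", label="ΔF/F")
        ax.plot(t_h, sp.surge_trace, lw=1.2, color="navy", label="30-min surge")
        for x, label in ((sp.onset_time, "onset"), (sp.peak_time, "peak"),
                         (sp.offset_time, "offset")):
            if x is not None:
                ax.axvline(x / 3600.0, color="crimson", ls=":", lw=0.8)
        ax.set(xlabel="time (h)", ylabel="ΔF/F (%)", title="surge decomposition")
        ax.legend(frameon=False)
        fig.tight_layout()
        path = outdir / "surge_decomposition.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def simulate_and_run(
    profile: str,
    duration_s: float,
    seed: int,
    outdir: Optional[Path] = None,
    **kwargs,
) -> PipelineResult:
    """Convenience wrapper: default config for ``profile`` → run_pipeline."""
    cfg = default_config(profile, duration_s=duration_s, seed=seed)
    return run_pipeline(cfg, outdir=outdir, **kwargs)
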