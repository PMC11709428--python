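"""Simulation configuration: parameter blocks and per-profile defaults.

Every tunable of the synthetic generator lives here.  Profiles bundle the
stage-specific statistics of GnRH dendron activity (inter-episode interval
distribution, episode kinetics, baseline-cluster structure, proestrus surge
shape, LH coupling) into a single :class:`SimConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

PROFILES = (
    "male",
    "metestrus",
    "diestrus",
    "proestrus",
    "estrus",
    "proestrus_surge",
    "misplaced_fiber",
)


class ConfigurationError(ValueError):
    """Raised when a SimConfig (or derived kernel calibration) is infeasible."""


def _skew_to_gamma_shape(skew: float) -> float:
    # gamma skewness = 2/sqrt(k)
    return (2.0 / skew) ** 2


@dataclass
class IntervalDist:
    """Inter-dSE interval distribution (minutes)."""

    family: str = "gamma"
    shape: float = _skew_to_gamma_shape(1.39)  # ~2.07, pins skewness at 1.39
    mean_min: float = 93.3
    trunc_min: Tuple[Optional[float], Optional[float]] = (3.9, None)

    def validate(self) -> None:
        if self.family != "gamma":
            raise ConfigurationError(
                f"unsupported interval distribution family: {self.family!r}"
            )
        if self.shape <= 0 or self.mean_min <= 0:
            raise ConfigurationError("interval shape and mean must be positive")


@dataclass
class DseShape:
    """dSE waveform: half-Gaussian rise, two-exponential decay.

    ``total_duration_s`` is the 5%-of-peak crossing-to-crossing extent; the
    decay's two time constants are solved numerically from the decay FWHM and
    the 5% crossing, with ``tail_fraction`` of the peak carried by the slow
    exponential.
    """

    amplitude_dff_pct: float = 20.0  # absolute dSE scale is unprinted; free
    rise_fwhm_s: float = 30.0
    decay_fwhm_s: float = 102.0
    total_duration_s: float = 658.0
    tail_fraction: float = 0.45
    amplitude_jitter_frac: float = 0.10
    kind: str = "skewed"  # or "gaussian" (symmetric, for calibration checks)
    sigma_s: float = 12.74  # used only by kind="gaussian"

    def validate(self) -> None:
        if self.kind not in ("skewed", "gaussian"):
            raise ConfigurationError(f"unknown dse kernel kind {self.kind!r}")
        if self.kind == "skewed" and not (
            0 < self.rise_fwhm_s < self.decay_fwhm_s < self.total_duration_s
        ):
            raise ConfigurationError(
                "dse shape requires rise_fwhm < decay_fwhm < total_duration"
            )
        if not 0 < self.tail_fraction < 1:
            raise ConfigurationError("tail_fraction must lie in (0,1)")


@dataclass
class BaselineCluster:
    """Low-amplitude clustered micro-activity between dSEs."""

    mean_cluster_duration_min: float = 22.5
    duration_gamma_shape: float = 8.0
    intra_cluster_freq_hz: float = 0.012  # mid printed range 0.006-0.018
    rel_amplitude_frac_of_dse: float = 0.11
    inter_cluster_gap_min_range: Tuple[float, float] = (8.0, 25.0)
    event_width_s: float = 40.0
    event_jitter_s: float = 8.0
    amplitude_jitter_frac: float = 0.2

    def validate(self) -> None:
        lo, hi = self.inter_cluster_gap_min_range
        if lo < 8.0:
            raise ConfigurationError(
                "inter-cluster gaps must be >= 8 min so the 420 s rule resolves them"
            )
        if hi < lo:
            raise ConfigurationError("inter_cluster_gap_min_range inverted")
        if not 0 <= self.rel_amplitude_frac_of_dse < 1:
            raise ConfigurationError("rel_amplitude_frac_of_dse must lie in [0,1)")
        if self.intra_cluster_freq_hz <= 0 or self.mean_cluster_duration_min <= 0:
            raise ConfigurationError("cluster frequency and duration must be positive")


@dataclass
class SurgeParams:
    """Slow proestrus surge envelope with superimposed ultradian oscillation."""

    onset_h_before_lights_off: float = 4.0
    onset_jitter_h: float = 0.75
    onset_to_peak_h: float = 5.9
    onset_to_offset_h: float = 12.6
    incline_fwhm_h: float = 3.1
    decline_fwhm_h: float = 4.7
    peak_dff_pct: Tuple[float, float] = (20.0, 40.0)
    osc_period_min: float = 78.0
    osc_period_sd_min: float = 20.0
    osc_period_range_min: Tuple[float, float] = (32.0, 150.0)
    osc_mod_depth: float = 0.5
    dse_suppression_h: float = 5.0
    foot_h: float = 0.5  # sub-detection rise before the nominal (5 pp) onset
    onset_detect_pp: float = 5.0  # envelope value at nominal onset

    def validate(self) -> None:
        if not (
            0
            < self.incline_fwhm_h
            < self.onset_to_peak_h
            < self.onset_to_offset_h
        ):
            raise ConfigurationError("surge timing anchors inconsistent")
        if self.decline_fwhm_h >= self.onset_to_offset_h - self.onset_to_peak_h:
            raise ConfigurationError("decline FWHM exceeds peak-to-offset span")
        lo, hi = self.peak_dff_pct
        if not 0 < lo <= hi:
            raise ConfigurationError("peak_dff_pct range invalid")
        if not 0 <= self.osc_mod_depth < 1:
            raise ConfigurationError("osc_mod_depth must lie in [0,1)")


@dataclass
class LHParams:
    """LH secretion coupling: basal level, dSE-locked pulses, surge gain."""

    basal_ng_ml: float = 0.3
    pulse_amp_ng_ml: float = 1.5
    peak_lag_min: float = 5.0
    clearance_halflife_min: float = 8.0
    surge_peak_ng_ml: float = 9.3
    surge_desensitization_h: float = 0.15  # sigmoid width, env-weighted hours
    surge_desens_delay_h: float = 1.6  # shutdown midpoint past peak exposure
    assay_sensitivity_ng_ml: float = 0.04
    assay_cv: float = 0.082

    def validate(self) -> None:
        if not 0 < self.assay_cv < 1:
            raise ConfigurationError("assay_cv must lie in (0,1)")
        if self.peak_lag_min <= 0 or self.clearance_halflife_min <= 0:
            raise ConfigurationError("LH timing parameters must be positive")


@dataclass
class BleachParams:
    """Photobleaching (single exponential) and raw-channel scales (a.u.)."""

    tau_s: float = 21600.0  # 6 h
    depth_frac: float = 0.2
    f0: float = 300.0  # initial 465 nm level, a.u.
    ref_level_frac: float = 0.4  # 405 level relative to f0
    ref_tau_factor: float = 1.0  # both channels share the bleach curve


@dataclass
class NoiseParams:
    sensor_sd: float = 0.3  # per-sample, in dF/F percentage points
    motion_artifact_rate_per_h: float = 2.0
    motion_artifact_amp_frac: float = 0.05  # of f0, shared between channels
    motion_artifact_width_s: float = 1.0


@dataclass
class Acquisition:
    mode: str = "continuous"  # or "scheduled"
    on_s: float = 5.0
    off_s: float = 10.0

    def validate(self, duration_s: float) -> None:
        if self.mode not in ("continuous", "scheduled"):
            raise ConfigurationError(f"unknown acquisition mode {self.mode!r}")
        if self.mode == "scheduled":
            cycle = self.on_s + self.off_s
            if cycle <= 0 or abs(duration_s / cycle - round(duration_s / cycle)) > 1e-9:
                raise ConfigurationError(
                    "scheduled mode requires on_s+off_s to divide the duration evenly"
                )


@dataclass
class SimConfig:
    profile_name: str = "male"
    sampling_rate: float = 10.0
    duration_s: float = 86400.0
    acquisition: Acquisition = field(default_factory=Acquisition)
    lights_on: str = "07:00"
    lights_off: str = "19:00"
    start_clock: str = "10:00"  # recordings start mid-morning
    interval_dist: IntervalDist = field(default_factory=IntervalDist)
    dse_shape: DseShape = field(default_factory=DseShape)
    baseline_cluster: BaselineCluster = field(default_factory=BaselineCluster)
    surge: Optional[SurgeParams] = None
    lh: LHParams = field(default_factory=LHParams)
    bleach: BleachParams = field(default_factory=BleachParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def validate(self) -> None:
        if self.profile_name not in PROFILES:
            raise ConfigurationError(f"unknown profile {self.profile_name!r}")
        if self.sampling_rate <= 0 or self.duration_s <= 0:
            raise ConfigurationError("sampling_rate and duration must be positive")
        self.acquisition.validate(self.duration_s)
        self.interval_dist.validate()
        self.dse_shape.validate()
        self.baseline_cluster.validate()
        self.lh.validate()
        if self.surge is not None:
            self.surge.validate()

    # -- clock helpers -------------------------------------------------
    def _clock_to_s(self, clock: str) -> float:
        hh, mm = clock.split(":")
        return 3600.0 * int(hh) + 60.0 * int(mm)

    @property
    def lights_off_s(self) -> float:
        """Seconds from recording start to lights-off (same or next day)."""
        off = self._clock_to_s(self.lights_off) - self._clock_to_s(self.start_clock)
        if off < 0:
            off += 86400.0
        return off

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        sub = {
            "acquisition": Acquisition,
            "interval_dist": IntervalDist,
            "dse_shape": DseShape,
            "baseline_cluster": BaselineCluster,
            "lh": LHParams,
            "bleach": BleachParams,
            "noise": NoiseParams,
        }
        for key, klass in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**_tupled(klass, d[key]))
        if d.get("surge") is not None and isinstance(d["surge"], dict):
            d["surge"] = SurgeParams(**_tupled(SurgeParams, d["surge"]))
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _tupled(klass, d: dict) -> dict:
    """JSON round-trips tuples as lists; restore tuple-typed fields."""
    out = dict(d)
    for f in dataclasses.fields(klass):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


# ----------------------------------------------------------------------
# Per-profile defaults.  Interval means and skewness, event kinetics,
# cluster durations and LH lags follow the stage-specific statistics the
# generator is calibrated to emulate.
# ----------------------------------------------------------------------

_FEMALE_KINETICS = dict(rise_fwhm_s=31.0, decay_fwhm_s=81.0, total_duration_s=463.0)

_STAGE_TABLE = {
    # profile: (interval mean min, skewness, cluster duration min, lag min)
    "male": (93.3, 1.39, 22.5, 5.0),
    "metestrus": (70.2, 0.83, 30.0, 6.1),
    "diestrus": (46.2, 1.37, 35.7, 6.1),
    "proestrus": (38.8, 1.13, 24.8, 6.1),
    "estrus": (151.0, 0.59, 35.3, 6.1),
}


def default_config(
    profile: str,
    duration_s: float = 86400.0,
    seed: int = 0,
    sampling_rate: float = 10.0,
    **overrides,
) -> SimConfig:
    """Build the default SimConfig for a named profile."""
    if profile not in PROFILES:
        raise ConfigurationError(f"unknown profile {profile!r}")

    stage = "proestrus" if profile == "proestrus_surge" else profile
    if profile == "misplaced_fiber":
        stage = "male"
    mean_min, skew, cluster_min, lag = _STAGE_TABLE[stage]

    interval = IntervalDist(
        shape=_skew_to_gamma_shape(skew),
        mean_min=mean_min,
        trunc_min=(3.9, None),
    )
    shape = DseShape() if stage == "male" else DseShape(**_FEMALE_KINETICS)
    cluster = BaselineCluster(
        mean_cluster_duration_min=cluster_min,
        rel_amplitude_frac_of_dse=0.11 if stage == "male" else 0.085,
    )
    lh = LHParams(peak_lag_min=lag)
    surge = SurgeParams() if profile == "proestrus_surge" else None

    if profile == "misplaced_fiber":
        shape = dataclasses.replace(shape, amplitude_dff_pct=0.0)
        cluster = dataclasses.replace(cluster, rel_amplitude_frac_of_dse=0.0)

    cfg = SimConfig(
        profile_name=profile,
        duration_s=float(duration_s),
        sampling_rate=float(sampling_rate),
        interval_dist=interval,
        dse_shape=shape,
        baseline_cluster=cluster,
        surge=surge,
        lh=lh,
        seed=int(seed),
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown SimConfig field {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg
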