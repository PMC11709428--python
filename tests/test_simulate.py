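"""Generator tests: kernel calibration, interval distributions, trace
assembly, ground-truth bookkeeping, and the coupled LH series."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sstats

import dendrosync as ds
from dendrosync.config import Acquisition, ConfigurationError, DseShape
from dendrosync.simulate import kernel_support


def _measure_kernel(shape, dt=0.05):
    """Independent oracle: crossing times of a densely rendered kernel."""
    pre, post = kernel_support(shape, cutoff=1e-4)
    t = np.arange(-pre, post, dt)
    y = ds.render_dse_kernel(shape, t)
    i_pk = int(np.argmax(y))

    def cross(level, side):
        if side == "left":
            idx = np.nonzero((y[:i_pk] <= level) & (y[1 : i_pk + 1] > level))[0]
            i = idx[-1]
        else:
            idx = np.nonzero((y[i_pk:-1] >= level) & (y[i_pk + 1 :] < level))[0]
            i = i_pk + idx[-1 if side == "right_last" else 0]
        frac = (y[i] - level) / (y[i] - y[i + 1]) if y[i] != y[i + 1] else 0.0
        return t[i] + frac * dt

    rise_fwhm = t[i_pk] - cross(0.5, "left")
    decay_fwhm = cross(0.5, "right") - t[i_pk]
    duration = cross(0.05, "right") - cross(0.05, "left")
    return rise_fwhm, decay_fwhm, duration


class TestDseKernel:
    def test_male_defaults_match_configured_measures(self):
        shape = DseShape()  # 30 / 102 / 658 s
        rise, decay, duration = _measure_kernel(shape)
        assert rise == pytest.approx(30.0, abs=0.2)
        assert decay == pytest.approx(102.0, abs=0.2)
        assert duration == pytest.approx(658.0, rel=0.02)

    def test_female_kinetics(self):
        shape = DseShape(rise_fwhm_s=31.0, decay_fwhm_s=81.0, total_duration_s=463.0)
        rise, decay, duration = _measure_kernel(shape)
        assert rise == pytest.approx(31.0, abs=0.2)
        assert decay == pytest.approx(81.0, abs=0.2)
        assert duration == pytest.approx(463.0, rel=0.02)

    def test_gaussian_mode_fwhm(self):
        # full FWHM of a Gaussian = 2*sqrt(2 ln 2)*sigma = 30.0 for sigma=12.74
        shape = DseShape(kind="gaussian", sigma_s=12.74)
        rise, decay, _ = _measure_kernel(shape)
        assert rise + decay == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 12.74, abs=0.1)
        assert rise == pytest.approx(decay, abs=0.1)

    def test_peak_is_unit(self):
        t = np.arange(-200, 1600, 0.1)
        y = ds.render_dse_kernel(DseShape(), t)
        assert np.max(y) == pytest.approx(1.0, abs=1e-6)

    def test_amplitude_invariance_of_widths(self):
        shape = DseShape()
        r1, d1, u1 = _measure_kernel(shape)
        # scaling the waveform by any A rescales the 50%/5% levels identically
        pre, post = kernel_support(shape, cutoff=1e-4)
        t = np.arange(-pre, post, 0.05)
        y = 7.3 * ds.render_dse_kernel(shape, t)
        half = 7.3 / 2
        i_pk = int(np.argmax(y))
        left = np.nonzero(y[:i_pk] <= half)[0][-1]
        assert t[i_pk] - t[left] == pytest.approx(r1, abs=0.1)

    def test_infeasible_shape_raises(self):
        with pytest.raises(ConfigurationError):
            _measure_kernel(DseShape(rise_fwhm_s=30, decay_fwhm_s=102, total_duration_s=140))
        with pytest.raises(ConfigurationError):
            DseShape(rise_fwhm_s=100, decay_fwhm_s=50, total_duration_s=658).validate()


class TestIntervals:
    def test_gamma_shape_pins_skewness(self):
        # analytic gamma skewness 2/sqrt(k): shape 4 -> 1.0
        assert 2.0 / math.sqrt(4.0) == 1.0
        cfg = ds.default_config("male")
        cfg.interval_dist.shape = 4.0
        cfg.interval_dist.trunc_min = (None, None)
        x = ds.draw_intervals(cfg, 200000, np.random.default_rng(0)) / 60.0
        assert sstats.skew(x) == pytest.approx(1.0, abs=0.03)

    def test_male_skewness_near_printed(self):
        cfg = ds.default_config("male")
        x = ds.draw_intervals(cfg, 5000, np.random.default_rng(3)) / 60.0
        assert sstats.skew(x) == pytest.approx(1.39, abs=0.15)

    @pytest.mark.parametrize(
        "profile,mean",
        [("male", 93.3), ("metestrus", 70.2), ("diestrus", 46.2),
         ("proestrus", 38.8), ("estrus", 151.0)],
    )
    def test_stage_mean_calibration(self, profile, mean):
        cfg = ds.default_config(profile)
        x = ds.draw_intervals(cfg, 10000, np.random.default_rng(7)) / 60.0
        assert np.mean(x) == pytest.approx(mean, rel=0.03)

    def test_truncation_respected(self):
        cfg = ds.default_config("male")
        x = ds.draw_intervals(cfg, 20000, np.random.default_rng(5)) / 60.0
        assert x.min() >= 3.9
        cfg.interval_dist.trunc_min = (10.0, 200.0)
        x = ds.draw_intervals(cfg, 20000, np.random.default_rng(5)) / 60.0
        assert x.min() >= 10.0 and x.max() <= 200.0

    def test_unsupported_family_raises(self):
        cfg = ds.default_config("male")
        cfg.interval_dist.family = "weibull"
        with pytest.raises(ConfigurationError):
            ds.draw_intervals(cfg, 10)


class TestAssembly:
    def test_determinism(self):
        cfg = ds.default_config("male", duration_s=3600, seed=42)
        r1, g1 = ds.assemble_trace(cfg)
        r2, g2 = ds.assemble_trace(cfg)
        np.testing.assert_array_equal(r1.f465, r2.f465)
        np.testing.assert_array_equal(r1.f405, r2.f405)
        np.testing.assert_array_equal(g1.dse_peak_times, g2.dse_peak_times)
        lh1 = ds.simulate_lh(g1, cfg, np.arange(300, 3600, 300))
        lh2 = ds.simulate_lh(g2, cfg, np.arange(300, 3600, 300))
        np.testing.assert_array_equal(lh1.concentrations, lh2.concentrations)

    def test_component_additivity(self):
        cfg = ds.default_config("proestrus_surge", duration_s=86400, seed=2)
        cfg.noise = dataclasses.replace(
            cfg.noise, sensor_sd=0.0, motion_artifact_rate_per_h=0.0
        )
        cfg.bleach = dataclasses.replace(cfg.bleach, depth_frac=0.0)
        raw, gt, comps = ds.assemble_trace(cfg, return_components=True)
        total = comps["dse"] + comps["baseline"] + comps["surge"]
        np.testing.assert_allclose(
            raw.f465, cfg.bleach.f0 * (1 + total / 100.0), rtol=1e-12
        )
        # disabling the baseline component removes exactly its contribution
        cfg2 = ds.default_config("proestrus_surge", duration_s=86400, seed=2)
        cfg2.noise = cfg.noise
        cfg2.bleach = cfg.bleach
        cfg2.baseline_cluster = dataclasses.replace(
            cfg2.baseline_cluster, rel_amplitude_frac_of_dse=0.0
        )
        raw2, _, comps2 = ds.assemble_trace(cfg2, return_components=True)
        assert np.all(comps2["baseline"] == 0.0)
        np.testing.assert_allclose(comps2["dse"], comps["dse"], rtol=1e-12)
        np.testing.assert_allclose(comps2["surge"], comps["surge"], rtol=1e-12)

    def test_ground_truth_invariants(self, male_trace_small):
        cfg, raw, gt = male_trace_small
        assert np.all(np.diff(gt.dse_peak_times) > 0)
        assert np.all((gt.dse_peak_times >= 0) & (gt.dse_peak_times <= cfg.duration_s))
        for s, e in gt.cluster_intervals:
            assert e > s
            # clusters avoid the dSE footprint
            for p in gt.dse_peak_times:
                assert e < p - 120.0 or s > p + 660.0
        # inter-cluster gaps resolvable by the 420 s rule
        for (s1, e1), (s2, e2) in zip(gt.cluster_intervals, gt.cluster_intervals[1:]):
            assert s2 - e1 > 420.0

    def test_micro_event_count_matches_freq(self):
        # 0.01 Hz over a 20-min cluster -> 12 recorded micro-events
        cfg = ds.default_config("male", duration_s=4 * 3600, seed=3)
        cfg.baseline_cluster = dataclasses.replace(
            cfg.baseline_cluster,
            intra_cluster_freq_hz=0.01,
            event_jitter_s=0.0,
            mean_cluster_duration_min=20.0,
            duration_gamma_shape=1e6,  # effectively fixed duration
        )
        series, intervals, events = ds.render_baseline_clusters(
            cfg, cfg.duration_s, np.arange(0, cfg.duration_s, 0.1), [],
            np.random.default_rng(0),
        )
        for s, e in intervals:
            n_in = np.sum((events >= s) & (events <= e))
            assert n_in == int((e - s) * 0.01)

    def test_zero_rel_amplitude_gives_flat_baseline(self):
        cfg = ds.default_config("male", duration_s=3600, seed=0)
        cfg.baseline_cluster = dataclasses.replace(
            cfg.baseline_cluster, rel_amplitude_frac_of_dse=0.0
        )
        series, intervals, events = ds.render_baseline_clusters(
            cfg, 3600, np.arange(0, 3600, 0.1), []
        )
        assert np.all(series == 0.0) and len(events) == 0

    def test_scheduled_mask(self):
        cfg = ds.default_config(
            "male", duration_s=3600, seed=1,
            acquisition=Acquisition(mode="scheduled", on_s=5, off_s=10),
        )
        raw, _ = ds.assemble_trace(cfg)
        t = raw.time
        expect = ((t % 15.0) < 5.0).astype(np.uint8)
        np.testing.assert_array_equal(raw.mask, expect)
        assert np.all(raw.f465[raw.mask == 0] == 0.0)

    def test_scheduled_requires_even_division(self):
        with pytest.raises(ConfigurationError):
            ds.default_config(
                "male", duration_s=3601,
                acquisition=Acquisition(mode="scheduled", on_s=5, off_s=10),
            )

    def test_misplaced_fiber_records_nothing(self):
        cfg = ds.default_config("misplaced_fiber", duration_s=4 * 3600, seed=5)
        raw, gt = ds.assemble_trace(cfg)
        assert len(gt.dse_peak_times) == 0
        assert len(gt.baseline_event_times) == 0

    def test_noiseless_single_dse_roundtrip(self):
        """With noise, motion and bleaching off, preprocessing recovers the
        injected kernel to numerical accuracy."""
        cfg = ds.default_config("male", duration_s=2 * 3600, seed=9)
        cfg.noise = dataclasses.replace(
            cfg.noise, sensor_sd=0.0, motion_artifact_rate_per_h=0.0
        )
        cfg.bleach = dataclasses.replace(cfg.bleach, depth_frac=0.0)
        cfg.baseline_cluster = dataclasses.replace(
            cfg.baseline_cluster, rel_amplitude_frac_of_dse=0.0
        )
        raw, gt, comps = ds.assemble_trace(cfg, return_components=True)
        dff = ds.preprocess(raw)
        assert np.max(np.abs(dff.dff - comps["dse"])) < 0.2


class TestSurgeEnvelope:
    def test_envelope_peak_in_printed_band(self):
        for seed in range(5):
            cfg = ds.default_config("proestrus_surge", seed=seed)
            t = np.arange(0, 86400, 0.1)
            env, troughs, info = ds.render_surge_envelope(cfg, t)
            assert 20.0 <= info["amplitude_pct"] <= 40.0

    def test_zero_mod_depth_is_smooth(self):
        cfg = ds.default_config("proestrus_surge", seed=1)
        cfg.surge = dataclasses.replace(cfg.surge, osc_mod_depth=0.0)
        t = np.arange(0, 86400, 0.1)
        env, troughs, info = ds.render_surge_envelope(cfg, t)
        assert len(troughs) == 0
        # single local maximum (smooth envelope)
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(env[env > 1e-9])))) > 1)
        assert sign_changes <= 1

    def test_trough_period_distribution(self):
        durations = []
        for seed in range(6):
            cfg = ds.default_config("proestrus_surge", seed=seed)
            t = np.arange(0, 86400, 0.1)
            _, troughs, _ = ds.render_surge_envelope(cfg, t)
            durations.extend(np.diff(troughs) / 60.0)
        assert np.mean(durations) == pytest.approx(78.0, abs=8.0)
        assert min(durations) >= 32.0 and max(durations) <= 150.0

    def test_envelope_crosses_detection_level_at_onset(self):
        cfg = ds.default_config("proestrus_surge", seed=4)
        cfg.surge = dataclasses.replace(cfg.surge, osc_mod_depth=0.0)
        t = np.arange(0, 86400, 0.1)
        env, _, info = ds.render_surge_envelope(cfg, t)
        i_on = int(info["onset_s"] / 0.1)
        assert env[i_on] == pytest.approx(cfg.surge.onset_detect_pp, abs=0.1)

    def test_dse_suppression_window(self):
        cfg = ds.default_config("proestrus_surge", duration_s=86400, seed=6)
        raw, gt = ds.assemble_trace(cfg)
        p0 = gt.surge_info["peak_s"]
        p1 = p0 + 3600.0 * cfg.surge.dse_suppression_h
        assert not np.any((gt.dse_peak_times >= p0) & (gt.dse_peak_times <= p1))


class TestLH:
    def test_basal_floor_without_events(self):
        cfg = ds.default_config("male", duration_s=7200, seed=0)
        gt = ds.GroundTruth(
            dse_peak_times=np.asarray([]), dse_amplitudes=np.asarray([]),
            cluster_intervals=[], baseline_event_times=np.asarray([]),
            surge_envelope=None, oscillation_trough_times=np.asarray([]),
            lh_pulse_peak_times=np.asarray([]), bleach_curve=np.asarray([]),
        )
        lh = ds.simulate_lh(gt, cfg, np.arange(300, 7200, 300))
        assert np.all(lh.concentrations >= cfg.lh.assay_sensitivity_ng_ml)
        assert np.median(lh.concentrations) == pytest.approx(cfg.lh.basal_ng_ml, rel=0.15)

    def test_single_dse_peak_lag_exact(self):
        cfg = ds.default_config("male", duration_s=7200, seed=0)
        gt = ds.GroundTruth(
            dse_peak_times=np.asarray([1800.0]), dse_amplitudes=np.asarray([20.0]),
            cluster_intervals=[], baseline_event_times=np.asarray([]),
            surge_envelope=None, oscillation_trough_times=np.asarray([]),
            lh_pulse_peak_times=np.asarray([2100.0]), bleach_curve=np.asarray([]),
        )
        dense = np.arange(0.0, 7200.0, 1.0)
        lh = ds.simulate_lh(gt, cfg, dense, noiseless=True)
        t_peak = dense[int(np.argmax(lh.concentrations))]
        assert t_peak == pytest.approx(1800.0 + 60.0 * cfg.lh.peak_lag_min, abs=1.5)

    def test_every_pulse_lags_by_peak_lag(self, male_trace_small):
        cfg, raw, gt = male_trace_small
        dense = np.arange(0.0, cfg.duration_s, 2.0)
        lh = ds.simulate_lh(gt, cfg, dense, noiseless=True)
        c = lh.concentrations
        for p in gt.dse_peak_times:
            lo = int((p + 60.0) / 2.0)
            hi = min(len(c), int((p + 600.0) / 2.0))
            if hi - lo < 10 or hi >= len(c) - 1:
                continue
            i_pk = lo + int(np.argmax(c[lo:hi]))
            assert dense[i_pk] - p == pytest.approx(60.0 * cfg.lh.peak_lag_min, abs=4.0)

    def test_empty_sampling_times(self, male_trace_small):
        cfg, raw, gt = male_trace_small
        lh = ds.simulate_lh(gt, cfg, [])
        assert len(lh.times) == 0
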