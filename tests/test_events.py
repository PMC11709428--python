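"""dSE detection, event kinetics, and interval-distribution statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dendrosync as ds
from dendrosync.config import DseShape
from dendrosync.events import DetectionParams, measure_event
from dendrosync.simulate import kernel_support
from dendrosync.types import DffTrace


def _flat_trace(duration_s=7200.0, fs=10.0, noise=0.0, rng=None):
    n = int(duration_s * fs)
    y = np.zeros(n)
    if noise and rng is not None:
        y += noise * rng.standard_normal(n)
    return DffTrace(time=np.arange(n) / fs, dff=y, sampling_rate=fs)


def _inject_kernel(trace, peak_time, amplitude, shape=None):
    shape = shape or DseShape()
    pre, post = kernel_support(shape)
    fs = trace.sampling_rate
    off = np.arange(-int(pre * fs), int(post * fs) + 1) / fs
    kern = ds.render_dse_kernel(shape, off)
    i0 = int(peak_time * fs) - int(pre * fs)
    trace.dff[i0 : i0 + len(kern)] += amplitude * kern
    return trace


class TestMeasureEvent:
    def test_triangular_pulse_geometry(self):
        fs = 10.0
        t = np.arange(0, 300, 1 / fs)
        y = np.maximum(0.0, 10.0 * (1.0 - np.abs(t - 150.0) / 50.0))
        i_pk = int(150 * fs)
        ev = measure_event(t, y, y, i_pk, 0.0, DetectionParams())
        assert ev.rise_fwhm == pytest.approx(25.0, abs=0.1)
        assert ev.decay_fwhm == pytest.approx(25.0, abs=0.1)
        # 5% crossings of a 50 s linear limb sit at 95% of the half-base
        assert ev.duration == pytest.approx(2 * 0.95 * 50.0, abs=0.2)

    def test_male_kernel_measures(self):
        shape = DseShape()
        fs = 10.0
        pre, post = kernel_support(shape, cutoff=1e-4)
        t = np.arange(0, pre + post + 200, 1 / fs)
        y = 20.0 * ds.render_dse_kernel(shape, t - (pre + 100))
        i_pk = int(np.argmax(y))
        ev = measure_event(t, y, y, i_pk, 0.0, DetectionParams())
        assert ev.rise_fwhm == pytest.approx(30.0, abs=0.2)
        assert ev.decay_fwhm == pytest.approx(102.0, abs=0.2)
        assert ev.duration == pytest.approx(658.0, abs=3.0)

    def test_gaussian_kernel_split_fwhm(self):
        fs = 10.0
        t = np.arange(0, 600, 1 / fs)
        y = 10.0 * np.exp(-((t - 300.0) ** 2) / (2 * 12.74**2))
        ev = measure_event(t, y, y, int(300 * fs), 0.0, DetectionParams())
        assert ev.rise_fwhm == pytest.approx(15.0, abs=0.1)
        assert ev.decay_fwhm == pytest.approx(15.0, abs=0.1)

    def test_truncated_event_flagged(self):
        fs = 10.0
        t = np.arange(0, 600, 1 / fs)
        y = np.linspace(0, 10, len(t))  # monotone: no pre-peak crossing region
        ev = measure_event(t, y, y, len(t) - 2, 0.0, DetectionParams())
        assert ev.truncated


class TestDetect:
    def test_flat_noise_yields_no_events(self, rng):
        trace = _flat_trace(noise=0.5, rng=rng)
        assert len(ds.detect_dse(trace)) == 0

    def test_short_trace_empty(self):
        trace = _flat_trace(duration_s=60.0)
        assert len(ds.detect_dse(trace)) == 0

    def test_scale_equivariance(self, rng):
        trace = _flat_trace(noise=0.2, rng=rng)
        for pk in (1800.0, 3600.0, 5400.0):
            _inject_kernel(trace, pk, 20.0)
        base = ds.detect_dse(trace, DetectionParams())
        c = 3.7
        scaled = DffTrace(time=trace.time, dff=c * trace.dff, sampling_rate=10.0)
        params = DetectionParams(prominence_pp=5.0 * c, amplitude_threshold_pp=5.0 * c)
        other = ds.detect_dse(scaled, params)
        np.testing.assert_allclose(base.peak_times, other.peak_times, atol=0.11)

    def test_sensitivity_precision_against_ground_truth(self):
        """>= 95% of ground-truth episodes recovered at +-30 s with >= 95%
        precision, across profiles."""
        total_gt = total_det = hits = 0
        for profile, dur, seeds in (
            ("male", 12 * 3600, (1, 2)),
            ("diestrus", 6 * 3600, (1, 2)),
            ("proestrus_surge", 86400, (1,)),
        ):
            for seed in seeds:
                from dendrosync.pipeline import simulate_and_run

                res = simulate_and_run(profile, dur, seed, with_lh=False)
                cfg = ds.default_config(profile, duration_s=dur, seed=seed)
                _, gt = ds.assemble_trace(cfg)
                det = res.events.peak_times
                total_gt += len(gt.dse_peak_times)
                total_det += len(det)
                hits += sum(
                    np.min(np.abs(det - p)) <= 30.0 if len(det) else False
                    for p in gt.dse_peak_times
                )
        assert hits / total_gt >= 0.95
        assert hits / total_det >= 0.95

    def test_slow_crest_rejected(self):
        # a 78-min sinusoidal crest is prominent but far too wide to be a dSE
        fs = 10.0
        t = np.arange(0, 4 * 4680.0, 1 / fs)
        y = 10.0 * np.sin(2 * np.pi * t / 4680.0)
        trace = DffTrace(time=t, dff=y, sampling_rate=fs)
        assert len(ds.detect_dse(trace)) == 0


class TestIntervalStatistics:
    def test_symmetric_sample_zero_skewness(self):
        stats = ds.interval_statistics([4.0, 8.0] * 10)
        assert stats.skewness == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_kurtosis_three(self, rng):
        x = rng.standard_normal(200000) * 5 + 50
        stats = ds.interval_statistics(x)
        assert stats.kurtosis_pearson == pytest.approx(3.0, abs=0.05)

    def test_gamma_sample_skewness(self, rng):
        k = (2.0 / 1.39) ** 2
        x = rng.gamma(k, 45.0, size=5000)
        stats = ds.interval_statistics(x)
        assert stats.skewness == pytest.approx(2.0 / math.sqrt(k), abs=0.15)

    @given(
        st.lists(st.floats(min_value=0.5, max_value=500.0), min_size=3, max_size=60)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_moments_match_brute_force(self, values):
        stats = ds.interval_statistics(values)
        x = np.asarray(values)
        mu = sum(x) / len(x)
        m2 = sum((v - mu) ** 2 for v in x) / len(x)
        m3 = sum((v - mu) ** 3 for v in x) / len(x)
        m4 = sum((v - mu) ** 4 for v in x) / len(x)
        if m2 <= 1e-12:
            return
        assert stats.skewness == pytest.approx(m3 / m2**1.5, rel=1e-9, abs=1e-9)
        assert stats.kurtosis_pearson == pytest.approx(m4 / m2**2, rel=1e-9, abs=1e-9)
        assert stats.kurtosis_pearson - stats.kurtosis_excess == 3.0

    def test_histogram_percentages(self):
        stats = ds.interval_statistics([5.0, 15.0, 15.0, 25.0])
        assert np.sum(stats.histogram_pct) == pytest.approx(100.0)
        assert stats.histogram_pct[1] == pytest.approx(50.0)

    def test_small_sample_moments_null(self):
        stats = ds.interval_statistics([5.0, 6.0])
        assert stats.skewness is None and stats.shapiro_w is None


class TestCompareStages:
    def test_identical_groups(self):
        groups = {k: [5.0, 5.0, 5.0] for k in "abcd"}
        out = ds.compare_stages(groups)
        assert out["H"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == 1.0
        assert all(p["p_adjusted"] > 0.05 for p in out["dunn"])

    def test_stage_effect_recovered(self, rng):
        means = {"metestrus": 70.2, "diestrus": 46.2, "proestrus": 38.8, "estrus": 151.0}
        samples = {
            k: rng.gamma(4.0, m / 4.0, size=40) for k, m in means.items()
        }
        out = ds.compare_stages(samples)
        sig = {
            frozenset(p["groups"]) for p in out["dunn"] if p["p_adjusted"] < 0.05
        }
        assert frozenset(("estrus", "diestrus")) in sig
        assert frozenset(("estrus", "proestrus")) in sig

    def test_dunn_z_matches_brute_force(self):
        a, b = [1.0, 2.0, 3.0], [101.0, 102.0, 103.0]
        out = ds.compare_stages({"a": a, "b": b})
        # independent oracle: midranks by enumeration
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        ra = np.mean([ranks[v] for v in a])
        rb = np.mean([ranks[v] for v in b])
        n = 6
        z = (ra - rb) / math.sqrt((n * (n + 1) / 12.0) * (1 / 3 + 1 / 3))
        assert out["dunn"][0]["z"] == pytest.approx(z, rel=1e-12)
        # exact permutation floor for n=3 vs 3 rank separation: 2/C(6,3)
        assert out["dunn"][0]["p_unadjusted"] < 2.0 / 20.0

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            ds.compare_stages({"a": [1, 2, 3], "b": [1]})


class TestMeanProfile:
    def test_identical_kernels_average_to_kernel(self):
        trace = _flat_trace(duration_s=3 * 3600)
        for pk in (2000.0, 5000.0, 8000.0):
            _inject_kernel(trace, pk, 20.0)
        series = ds.detect_dse(trace)
        prof = ds.mean_event_profile(series, trace)
        shape = DseShape()
        expected = 20.0 * ds.render_dse_kernel(shape, prof["offset_s"])
        assert np.max(np.abs(prof["mean_dff"] - expected)) < 0.5

    def test_amplitude_linearity(self):
        trace = _flat_trace(duration_s=3 * 3600)
        amps = (15.0, 20.0, 25.0)
        for pk, a in zip((2000.0, 5000.0, 8000.0), amps):
            _inject_kernel(trace, pk, a)
        series = ds.detect_dse(trace)
        prof = ds.mean_event_profile(series, trace)
        assert np.max(prof["mean_dff"]) == pytest.approx(np.mean(amps), rel=0.02)

    def test_requires_two_events(self):
        trace = _flat_trace()
        _inject_kernel(trace, 3600.0, 20.0)
        series = ds.detect_dse(trace)
        with pytest.raises(ValueError):
            ds.mean_event_profile(series, trace)
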