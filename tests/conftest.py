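"""Shared fixtures: expensive simulated cohorts are session-scoped so the
acceptance tests and unit tests can reuse them."""

from __future__ import annotations

import time

import numpy as np
import pytest

import dendrosync as ds
from dendrosync.pipeline import AnalysisParams, simulate_and_run


@pytest.fixture(scope="session")
def male_runs():
    """Five simulated 24-h male recordings (seeds 1-5) through the full
    pipeline, with wall time recorded."""
    t0 = time.monotonic()
    runs = [
        simulate_and_run("male", 86400.0, seed, with_lh=False) for seed in range(1, 6)
    ]
    elapsed = time.monotonic() - t0
    return {"runs": runs, "elapsed_s": elapsed}


@pytest.fixture(scope="session")
def male_ground_truths():
    return [ds.assemble_trace(ds.default_config("male", 86400.0, seed))[1] for seed in range(1, 6)]


@pytest.fixture(scope="session")
def proestrus_runs():
    """Ten simulated 24-h proestrus recordings (seeds 1-10) with LH sampled
    every 3 h over 18 h."""
    t0 = time.monotonic()
    params = AnalysisParams(lh_sampling_interval_s=10800.0, lh_span_s=18 * 3600.0)
    runs = [
        simulate_and_run("proestrus_surge", 86400.0, seed, params=params)
        for seed in range(1, 11)
    ]
    elapsed = time.monotonic() - t0
    return {"runs": runs, "elapsed_s": elapsed}


@pytest.fixture(scope="session")
def male_trace_small():
    """One 4-h male trace with ground truth (for quick unit checks)."""
    cfg = ds.default_config("male", duration_s=4 * 3600.0, seed=11)
    raw, gt = ds.assemble_trace(cfg)
    return cfg, raw, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
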