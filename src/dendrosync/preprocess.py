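"""Raw two-channel photometry → baseline-corrected ΔF/F (%).

Chain: (scheduled traces are first collapsed to one sample per on/off cycle)
reference subtraction using the calcium-independent 405 nm channel, a robust
single-exponential photobleaching fit, then
ΔF/F = (F_recorded − F_baseline) / F_baseline × 100.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy.optimize import least_squares, minimize

from .types import BaselineFit, DffTrace, RawPhotometry


def subtract_reference(raw: RawPhotometry, mode: str = "scaled") -> Tuple[np.ndarray, dict]:
    """Remove shared (motion) artifacts using the 405 nm channel.

    ``scaled`` (default): least-squares fit of the 405 channel to the 465
    channel, subtract the fitted reference and re-add its mean so the signal
    stays positive.  ``direct``: plain 465 − 405.
    Returns (corrected signal, reference fit dict).
    """
    if mode not in ("scaled", "direct"):
        raise ValueError(f"unknown reference mode {mode!r}")
    on = raw.mask.astype(bool)
    f465 = np.asarray(raw.f465, float)
    f405 = np.asarray(raw.f405, float)
    if mode == "scaled" and np.allclose(f405[on], 0.0):
        warnings.warn("405 channel is all zero; falling back to direct subtraction")
        mode = "direct"
    if mode == "direct":
        sig = f465 - f405
        return sig, {"mode": "direct", "slope": 1.0, "intercept": 0.0}
    x = f405[on]
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, f465[on], rcond=None)
    fitted = slope * f405 + intercept
    sig = f465 - fitted + float(np.mean(fitted[on]))
    return sig, {"mode": "scaled", "slope": float(slope), "intercept": float(intercept)}


def fit_bleach(
    time: np.ndarray,
    signal: np.ndarray,
    block_s: float = 60.0,
    quantile: float = 0.15,
) -> BaselineFit:
    """Robust single-exponential baseline fit a·exp(−t/τ) + c.

    The curve is fitted to blockwise medians by quantile (pinball-loss)
    regression at a low quantile, so that calcium transients and a slow
    surge — both strictly positive excursions that can occupy a large
    fraction of the recording — pull the baseline up only marginally.
    Falls back to a constant low-quantile baseline if the fit fails.
    """
    t = np.asarray(time, float)
    y = np.asarray(signal, float)
    if t[-1] - t[0] < 1800.0:
        raise ValueError("bleach fit requires at least 30 min of signal")

    n_per = max(2, int(round(block_s * (len(t) - 1) / (t[-1] - t[0]))))
    n_blocks = len(t) // n_per
    yb = np.median(y[: n_blocks * n_per].reshape(n_blocks, n_per), axis=1)
    tb = t[: n_blocks * n_per].reshape(n_blocks, n_per).mean(axis=1)

    span = tb[-1] - tb[0]
    head = max(2, len(yb) // 20)
    a0 = float(np.median(yb[:head]) - np.median(yb[-head:]))
    c0 = float(np.median(yb[-head:]))
    scale = max(float(np.std(yb)), 1e-9)

    def pinball(params):
        a, logtau, c = params
        r = yb - (a * np.exp(-tb / np.exp(logtau)) + c)
        return float(np.mean(np.where(r >= 0, quantile * r, (quantile - 1.0) * r)))

    best = None
    for tau0 in (span / 6.0, span / 2.0):
        res = minimize(
            pinball,
            np.array([a0 if abs(a0) > 1e-12 else 0.01 * scale, np.log(tau0), c0]),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        warnings.warn("bleach fit did not converge; using constant baseline")
        return BaselineFit(a=0.0, tau_s=0.0, c=float(np.percentile(y, 10)), converged=False)

    # refine on baseline blocks only: the pinball curve is a global quantile
    # and can under-fit an early decay when a surge occupies the mid-trace,
    # so clip elevated blocks (asymmetrically) and re-fit by least squares
    p = np.array(
        [best.x[0], float(np.clip(np.exp(best.x[1]), span / 199.0, span * 199.0)), best.x[2]]
    )
    success = bool(best.success)
    for _ in range(3):
        resid = yb - (p[0] * np.exp(-tb / p[1]) + p[2])
        low = resid[resid <= np.percentile(resid, 40)]
        center = float(np.median(low))
        sd = 1.4826 * float(np.median(np.abs(low - center))) + 1e-9
        keep = resid < center + 4.0 * sd
        if keep.sum() < max(10, len(tb) // 10):
            break
        res2 = least_squares(
            lambda q, m=keep: q[0] * np.exp(-tb[m] / q[1]) + q[2] - yb[m],
            p,
            bounds=([-np.inf, span / 200.0, -np.inf], [np.inf, span * 200.0, np.inf]),
            max_nfev=200,
        )
        p = res2.x
        success = bool(res2.success)
    return BaselineFit(a=float(p[0]), tau_s=float(p[1]), c=float(p[2]), converged=success)


def compute_dff(time: np.ndarray, signal: np.ndarray, baseline: BaselineFit) -> np.ndarray:
    """ΔF/F = (F_recorded − F_baseline) / F_baseline × 100."""
    base = baseline.evaluate(time)
    if np.any(base <= 0):
        bad = int(np.argmax(base <= 0))
        raise ValueError(
            f"baseline is non-positive at t={float(np.asarray(time)[bad]):.1f} s"
        )
    return (np.asarray(signal, float) - base) / base * 100.0


def regularize_scheduled(raw: RawPhotometry) -> RawPhotometry:
    """Collapse each on-window of a scheduled trace to its mean.

    Output is uniform at one sample per on/off cycle, timestamped at the
    on-window centre.  Continuous traces pass through unchanged.
    """
    mask = raw.mask.astype(bool)
    if mask.all():
        return raw
    starts = np.flatnonzero(mask & ~np.roll(mask, 1))
    if mask[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    lengths = []
    windows = []
    for s in starts:
        e = s
        while e < len(mask) and mask[e]:
            e += 1
        windows.append((s, e))
        lengths.append(e - s)
    if len(set(lengths[:-1] if len(lengths) > 1 else lengths)) > 1:
        raise ValueError("aperiodic acquisition mask")
    if len(starts) > 2:
        cyc = np.diff(starts)
        if len(set(cyc[:-1].tolist())) > 1:
            raise ValueError("aperiodic acquisition mask")
    t = np.asarray(raw.time)
    new_t = np.asarray([0.5 * (t[s] + t[e - 1]) for s, e in windows])
    new465 = np.asarray([raw.f465[s:e].mean() for s, e in windows])
    new405 = np.asarray([raw.f405[s:e].mean() for s, e in windows])
    fs = 1.0 / float(np.median(np.diff(new_t))) if len(new_t) > 1 else raw.sampling_rate
    return RawPhotometry(
        time=new_t,
        f465=new465,
        f405=new405,
        mask=np.ones(len(new_t), np.uint8),
        sampling_rate=fs,
        metadata=dict(raw.metadata, regularized="true"),
    )


def preprocess(raw: RawPhotometry, mode: str = "scaled") -> DffTrace:
    """Full chain: regularize (if scheduled) → reference → bleach fit → ΔF/F."""
    work = regularize_scheduled(raw)
    sig, ref_fit = subtract_reference(work, mode=mode)
    baseline = fit_bleach(work.time, sig)
    if not baseline.converged:
        baseline = BaselineFit(
            a=0.0, tau_s=0.0, c=float(np.percentile(sig, 10)), converged=False
        )
    dff = compute_dff(work.time, sig, baseline)
    return DffTrace(
        time=work.time,
        dff=dff,
        sampling_rate=work.sampling_rate,
        baseline_fit=baseline,
        reference_fit=ref_fit,
        provenance={"reference_mode": ref_fit["mode"]},
        metadata=dict(work.metadata),
    )
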