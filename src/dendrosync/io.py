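"""File formats: TSV (canonical interchange) and optional HDF5.

Trace schema: columns time_s, f465, f405, mask; '#'-prefixed header lines
carry sampling rate and metadata.  All numeric parsing is locale-independent
(dot decimal).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import h5py
import numpy as np
import pandas as pd

from .lh import LHSeries
from .types import DffTrace, RawPhotometry

_TRACE_COLUMNS = ["time_s", "f465", "f405", "mask"]


def write_trace(path, raw: RawPhotometry, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as h5:
            for name, arr in (
                ("time_s", raw.time),
                ("f465", raw.f465),
                ("f405", raw.f405),
                ("mask", raw.mask),
            ):
                h5.create_dataset(name, data=arr)
            h5.attrs["sampling_rate_hz"] = raw.sampling_rate
            for k, v in raw.metadata.items():
                h5.attrs[k] = v
        return
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {raw.sampling_rate!r}\n")
        for k, v in raw.metadata.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(_TRACE_COLUMNS) + "\n")
        np.savetxt(
            fh,
            np.column_stack([raw.time, raw.f465, raw.f405, raw.mask]),
            fmt=["%.6f", "%.10g", "%.10g", "%d"],
            delimiter="\t",
        )


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    return meta


def read_trace(path, fmt: str = None) -> RawPhotometry:
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix in (".h5", ".hdf5") else "tsv"
    if fmt == "hdf5":
        with h5py.File(path, "r") as h5:
            data = {name: h5[name][:] for name in _TRACE_COLUMNS}
            fs = float(h5.attrs["sampling_rate_hz"])
            meta = {
                k: str(v)
                for k, v in h5.attrs.items()
                if k != "sampling_rate_hz"
            }
    else:
        meta = _read_header(path)
        fs = float(meta.pop("sampling_rate_hz", 0) or 0)
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace file missing column(s): {', '.join(missing)}")
        data = {c: df[c].to_numpy() for c in _TRACE_COLUMNS}
        if fs == 0 and len(data["time_s"]) > 1:
            fs = 1.0 / float(np.median(np.diff(data["time_s"])))
    mask = data["mask"].astype(np.uint8)
    if mask.all() and len(data["time_s"]) > 2:
        steps = np.diff(data["time_s"])
        if np.max(np.abs(steps - steps[0])) > 1e-6 * max(1.0, abs(steps[0])):
            raise ValueError("continuous-mode trace has a nonuniform time grid")
    return RawPhotometry(
        time=np.asarray(data["time_s"], float),
        f465=np.asarray(data["f465"], float),
        f405=np.asarray(data["f405"], float),
        mask=mask,
        sampling_rate=fs,
        metadata=meta,
    )


def write_dff(path, dff: DffTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {dff.sampling_rate!r}\n")
        for k, v in dff.metadata.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_s\tdff_pct\n")
        np.savetxt(
            fh,
            np.column_stack([dff.time, dff.dff]),
            fmt=["%.6f", "%.8g"],
            delimiter="\t",
        )


def read_dff(path) -> DffTrace:
    meta = _read_header(path)
    fs = float(meta.pop("sampling_rate_hz", 0) or 0)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "time_s" not in df.columns or "dff_pct" not in df.columns:
        raise ValueError("dff file requires columns time_s, dff_pct")
    t = df["time_s"].to_numpy(float)
    if fs == 0 and len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    return DffTrace(
        time=t, dff=df["dff_pct"].to_numpy(float), sampling_rate=fs, metadata=meta
    )


def write_lh(path, lh: LHSeries) -> None:
    with open(path, "w") as fh:
        fh.write("time_s\tlh_ng_ml\n")
        np.savetxt(
            fh,
            np.column_stack([lh.times, lh.concentrations]),
            fmt=["%.1f", "%.6g"],
            delimiter="\t",
        )


def read_lh(path) -> LHSeries:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "time_s" not in df.columns or "lh_ng_ml" not in df.columns:
        raise ValueError("LH file requires columns time_s, lh_ng_ml")
    t = df["time_s"].to_numpy(float)
    interval = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    return LHSeries(
        times=t, concentrations=df["lh_ng_ml"].to_numpy(float), sampling_interval=interval
    )


def write_events(path, series) -> None:
    rows = []
    for ev in series.events:
        rows.append(
            {
                "peak_time_s": ev.peak_time,
                "peak_amplitude_pct": ev.peak_amplitude,
                "local_baseline_pct": ev.local_baseline,
                "onset_time_s": ev.onset_time,
                "offset_time_s": ev.offset_time,
                "duration_s": ev.duration,
                "rise_fwhm_s": ev.rise_fwhm,
                "decay_fwhm_s": ev.decay_fwhm,
                "truncated": ev.truncated,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "peak_time_s",
            "peak_amplitude_pct",
            "local_baseline_pct",
            "onset_time_s",
            "offset_time_s",
            "duration_s",
            "rise_fwhm_s",
            "decay_fwhm_s",
            "truncated",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_clusters(path, clusters: List) -> None:
    rows = []
    for c in clusters:
        rows.append(
            {
                "start_time_s": c.start_time,
                "end_time_s": c.end_time,
                "duration_min": c.duration_min,
                "n_peaks": c.n_peaks,
                "intra_cluster_frequency_hz": c.intra_cluster_frequency_hz,
                "mean_peak_amplitude_pct": c.mean_peak_amplitude,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "start_time_s",
            "end_time_s",
            "duration_min",
            "n_peaks",
            "intra_cluster_frequency_hz",
            "mean_peak_amplitude_pct",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
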