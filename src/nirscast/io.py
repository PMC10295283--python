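"""File readers and writers: delimited text time series, SNIRF, exports.

CSV is the primary interchange format (header mandatory, ``time_s`` plus one
column per signal).  SNIRF (HDF5) recordings are read-only: the oxyhemoglobin
channel is picked by index or by dataTypeLabel.  Every stochastic artifact is
written next to a JSON manifest recording the seeds that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .modwt import MraComponents
from .signal import Signal1D
from .synthetic import SyntheticRecord

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "export_decomposition",
    "read_decomposition",
    "export_dataset",
    "write_manifest",
]

_REL_DT_TOL = 1e-3     # relative tolerance on timestamp spacing


def _fs_from_time(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _REL_DT_TOL * med:
        raise ValueError("non-uniform sampling: timestamp gaps exceed tolerance")
    return 1.0 / med


def read_timeseries(path: str | Path, fmt: str | None = None,
                    channel: int | str | None = None,
                    fs: float | None = None) -> Signal1D:
    """Read a single-channel time series from CSV/TSV or SNIRF.

    CSV needs a header; a ``time_s`` column (if present) must be uniformly
    sampled and determines ``fs`` unless one is supplied.  For SNIRF,
    ``channel`` selects a column of dataTimeSeries by index, or by matching
    the measurementList dataTypeLabel (e.g. "HbO").
    """
    path = Path(path)
    if fmt is None:
        fmt = "snirf" if path.suffix.lower() == ".snirf" else "csv"
    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        cols = list(df.columns)
        if "time_s" in cols:
            t = df["time_s"].to_numpy(dtype=float)
            derived = _fs_from_time(t)
            fs = derived if fs is None else fs
            cols.remove("time_s")
        elif fs is None:
            raise ValueError("no time_s column: a sampling rate is required")
        if channel is None:
            name = cols[0]
        elif isinstance(channel, int):
            name = cols[channel]
        else:
            name = channel
        return Signal1D(df[name].to_numpy(dtype=float), fs, label=str(name))
    if fmt == "snirf":
        return _read_snirf(path, channel, fs)
    raise ValueError(f"unknown format: {fmt!r}")


def _read_snirf(path: Path, channel: int | str | None,
                fs: float | None) -> Signal1D:
    with h5py.File(path, "r") as f:
        data = f["/nirs/data1/dataTimeSeries"][()]
        t = np.asarray(f["/nirs/data1/time"][()], dtype=float).ravel()
        if data.ndim == 1:
            data = data[:, None]
        idx = 0
        label = None
        if isinstance(channel, int):
            idx = channel
        elif isinstance(channel, str):
            grp = f["/nirs/data1"]
            matches = []
            for key in sorted(k for k in grp if k.startswith("measurementList")):
                ml = grp[key]
                if "dataTypeLabel" in ml:
                    lab = ml["dataTypeLabel"][()]
                    lab = lab.decode() if isinstance(lab, bytes) else str(lab)
                    if channel.lower() in lab.lower():
                        matches.append(int(key[len("measurementList"):]) - 1)
            if not matches:
                raise ValueError(f"no SNIRF channel with dataTypeLabel ~ {channel!r}")
            idx = matches[0]
            label = channel
    if t.size == 2 and data.shape[0] > 2:          # [start, dt] convention
        rate = 1.0 / float(t[1])
    else:
        rate = _fs_from_time(t)
    return Signal1D(data[:, idx], fs if fs is not None else rate,
                    label=label or f"snirf_ch{idx}")


def write_timeseries(signal: Signal1D, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": signal.times, "value": signal.samples})
    df.to_csv(path, index=False)


def export_decomposition(components: MraComponents, fs: float,
                         path: str | Path) -> None:
    """Wide CSV: time_s, D1..DJ, AJ — one row per sample."""
    J = components.levels
    data = {"time_s": np.arange(components.approximation.size) / fs}
    for j in range(1, J + 1):
        data[f"D{j}"] = components.details[j - 1]
    data[f"A{J}"] = components.approximation
    pd.DataFrame(data).to_csv(path, index=False)


def read_decomposition(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("decomposition CSV must carry a time_s column")
    return df


def export_dataset(records: list[SyntheticRecord], outdir: str | Path) -> Path:
    """One CSV per record (combined + each labeled component) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for i, rec in enumerate(records):
        data = {"time_s": rec.combined.times, "combined": rec.combined.samples}
        for name, comp in rec.components.items():
            data[name] = comp.samples
        pd.DataFrame(data).to_csv(outdir / f"record_{i:04d}.csv", index=False)
        row = {"record_id": i, "seed": rec.seed, "has_dhrf": rec.has_dhrf,
               "fs": rec.fs, "rest_samples": rec.rest_samples}
        row.update(rec.draws)
        manifest_rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    return manifest


def write_manifest(path: str | Path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, default=str))
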