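"""Readers and writers for the formats the pipelines touch.

Calcium movies: multi-page TIFF plus a JSON sidecar, or a single HDF5 file
(`/movie`, `/ground_truth/*`, metadata as attributes). MEA recordings:
HDF5 with `/raw` (channels x samples, float32 uV) and `fs_hz` /
`stim_times_s` attributes. Spike trains: CSV with `electrode,time_s`
columns. Run configs: strict YAML (JSON accepted).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import CalciumMovie, MEARecording, SpikeTrainSet


# ---------------------------------------------------------------------------
# calcium movies


def write_movie(movie: CalciumMovie, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("movie", data=movie.data)
            d.attrs["frame_rate_hz"] = movie.frame_rate
            d.attrs["stim_times_s"] = movie.stim_times
    else:
        tifffile.imwrite(path, movie.data.astype(np.float32))
        sidecar = {
            "frame_rate_hz": movie.frame_rate,
            "stim_times_s": movie.stim_times.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_movie(path: str | Path, frame_rate: float | None = None) -> CalciumMovie:
    """Load a movie; `frame_rate` overrides/substitutes missing metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            d = f["movie"]
            data = d[...]
            fr = frame_rate or d.attrs.get("frame_rate_hz")
            stim = np.asarray(d.attrs.get("stim_times_s", []))
    else:
        data = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        fr, stim = frame_rate, np.array([])
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fr = frame_rate or meta.get("frame_rate_hz")
            stim = np.asarray(meta.get("stim_times_s", []))
    if fr is None:
        raise ValueError(
            f"{path}: no frame_rate metadata; pass frame_rate= explicitly"
        )
    return CalciumMovie(np.asarray(data, dtype=float), float(fr), stim)


# ---------------------------------------------------------------------------
# MEA recordings


def write_recording(rec: MEARecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("raw", data=rec.raw.astype(np.float32))
        d.attrs["fs_hz"] = rec.fs
        d.attrs["stim_times_s"] = rec.stim_times
        d.attrs["electrode_ids"] = [e.encode() for e in rec.electrode_ids]


def read_recording(path: str | Path) -> MEARecording:
    with h5py.File(path, "r") as f:
        d = f["raw"]
        raw = d[...]
        fs = float(d.attrs["fs_hz"])
        stim = np.asarray(d.attrs.get("stim_times_s", []))
        raw_ids = d.attrs.get("electrode_ids", [])
        ids = [e.decode() if isinstance(e, bytes) else str(e) for e in raw_ids] or None
    return MEARecording(raw, fs, stim, electrode_ids=ids)


# ---------------------------------------------------------------------------
# spike-time tables


def write_spike_table(trains: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        {"electrode": e, "time_s": t}
        for e, times in trains.trains.items()
        for t in times
    ]
    pd.DataFrame(rows, columns=["electrode", "time_s"]).to_csv(path, index=False)


def read_spike_table(path: str | Path, duration: float | None = None) -> SpikeTrainSet:
    """CSV with columns electrode,time_s -> SpikeTrainSet.

    Rows are sorted per electrode; duplicate timestamps on one electrode
    are collapsed with a warning. `duration` defaults to the last spike
    time (use the flag when the recording outlasts the last spike).
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["electrode", "time_s"]:
        raise ValueError("spike table must have columns electrode,time_s")
    if len(df) and (df["time_s"] < 0).any():
        raise ValueError("negative spike time in table")
    trains = {}
    for e, grp in df.groupby("electrode"):
        t = np.sort(grp["time_s"].to_numpy(dtype=float))
        uniq = np.unique(t)
        if uniq.size < t.size:
            import warnings

            warnings.warn(f"duplicate spike times on {e} collapsed", stacklevel=2)
        trains[str(e)] = uniq
    if duration is None:
        duration = max((t[-1] for t in trains.values() if t.size), default=0.0) + 1e-9
    return SpikeTrainSet(trains, float(duration))


# ---------------------------------------------------------------------------
# configs and reports


def read_config(path: str | Path, allowed_keys: set[str] | None = None) -> dict:
    """Strict YAML/JSON config loader; unknown keys are rejected."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - allowed_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_json_report(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
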