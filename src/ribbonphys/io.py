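"""File-format round-trips for the synthetic recordings and results.

Sweeps and capacitance tracks are stored in HDF5 (groups /protocol,
/current, /leak, /cm); movies and two-channel stacks as multi-page TIFF
with a YAML sidecar carrying acquisition metadata; truth tables and tidy
results as CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .protocols import VoltageProtocol
from .synth.abr import ABRSeries
from .synth.capacitance import CapacitanceRecording
from .synth.currents import CurrentSweep
from .synth.hotspot import HotspotMovie
from .synth.puncta import PunctaStack

__all__ = [
    "save_sweep",
    "load_sweep",
    "save_capacitance",
    "load_capacitance",
    "save_movie",
    "load_movie",
    "save_stack",
    "load_stack",
    "save_abr",
    "load_abr",
    "puncta_table",
]


def _write_protocol(grp: h5py.Group, proto: VoltageProtocol) -> None:
    grp.create_dataset("segments", data=np.asarray(proto.segments, dtype=float))
    grp.attrs["sample_interval"] = proto.sample_interval
    grp.attrs["holding"] = proto.holding
    grp.attrs["label"] = proto.label
    if proto.analysis_window is not None:
        grp.attrs["analysis_window"] = list(proto.analysis_window)


def _read_protocol(grp: h5py.Group) -> VoltageProtocol:
    segs = tuple(tuple(row) for row in grp["segments"][()])
    win = grp.attrs.get("analysis_window")
    return VoltageProtocol(
        sample_interval=float(grp.attrs["sample_interval"]),
        segments=segs,
        holding=float(grp.attrs["holding"]),
        label=str(grp.attrs["label"]),
        analysis_window=tuple(win) if win is not None else None,
    )


def save_sweep(path, sweep: CurrentSweep) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=sweep.time)
        f.create_dataset("voltage", data=sweep.voltage)
        f.create_dataset("current", data=sweep.current)
        leak = f.create_group("leak")
        for i, ls in enumerate(sweep.leak_sweeps):
            leak.create_dataset(str(i), data=ls)
        if sweep.protocol is not None:
            _write_protocol(f.create_group("protocol"), sweep.protocol)
        meta = f.create_group("meta")
        for key in ("noise_sd", "ljp", "n_leak"):
            if key in sweep.meta:
                meta.attrs[key] = sweep.meta[key]


def load_sweep(path) -> CurrentSweep:
    with h5py.File(path, "r") as f:
        leak = tuple(f["leak"][k][()] for k in sorted(f["leak"], key=int))
        proto = _read_protocol(f["protocol"]) if "protocol" in f else None
        return CurrentSweep(
            time=f["time"][()],
            voltage=f["voltage"][()],
            current=f["current"][()],
            leak_sweeps=leak,
            protocol=proto,
            meta=dict(f["meta"].attrs) if "meta" in f else {},
        )


def save_capacitance(path, rec: CapacitanceRecording) -> None:
    with h5py.File(path, "w") as f:
        cm = f.create_group("cm")
        cm.create_dataset("time", data=rec.time)
        cm.create_dataset("c_m", data=rec.c_m)
        f.create_dataset("current", data=rec.current)
        f.attrs["pulse_window"] = list(rec.pulse_window)
        if "delta_cm" in rec.truth:
            f.attrs["truth_delta_cm"] = rec.truth["delta_cm"]
            f.attrs["truth_duration"] = rec.truth["duration"]


def load_capacitance(path) -> CapacitanceRecording:
    with h5py.File(path, "r") as f:
        truth = {}
        if "truth_delta_cm" in f.attrs:
            truth = {
                "delta_cm": float(f.attrs["truth_delta_cm"]),
                "duration": float(f.attrs["truth_duration"]),
            }
        return CapacitanceRecording(
            time=f["cm/time"][()],
            c_m=f["cm/c_m"][()],
            current=f["current"][()],
            pulse_window=tuple(f.attrs["pulse_window"]),
            truth=truth,
        )


def save_movie(path, movie: HotspotMovie) -> None:
    """Write both ramp movies as one multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    frames = np.concatenate([movie.frames_a, movie.frames_b]).astype(np.float32)
    tifffile.imwrite(path, frames)
    meta = {
        "n_frames_per_ramp": int(movie.frames_a.shape[0]),
        "frame_interval_ms": float(movie.frame_interval),
        "pixel_size_um": float(movie.pixel_size),
        "onset_a_ms": float(movie.onset_a),
        "onset_b_ms": float(movie.onset_b),
        "n_baseline": int(movie.n_baseline),
        "ramp_a": {
            "sample_interval": movie.ramp_a.sample_interval,
            "segments": [list(s) for s in movie.ramp_a.segments],
            "holding": movie.ramp_a.holding,
            "analysis_window": list(movie.ramp_a.analysis_window),
        },
        "ramp_b": {
            "sample_interval": movie.ramp_b.sample_interval,
            "segments": [list(s) for s in movie.ramp_b.segments],
            "holding": movie.ramp_b.holding,
            "analysis_window": list(movie.ramp_b.analysis_window),
        },
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_movie(path) -> HotspotMovie:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    n = meta["n_frames_per_ramp"]

    def ramp(key):
        r = meta[key]
        return VoltageProtocol(
            sample_interval=float(r["sample_interval"]),
            segments=tuple(tuple(s) for s in r["segments"]),
            holding=float(r["holding"]),
            label="ramp",
            analysis_window=tuple(r["analysis_window"]),
        )

    return HotspotMovie(
        frames_a=frames[:n],
        frames_b=frames[n:],
        frame_interval=float(meta["frame_interval_ms"]),
        pixel_size=float(meta["pixel_size_um"]),
        ramp_a=ramp("ramp_a"),
        ramp_b=ramp("ramp_b"),
        onset_a=float(meta["onset_a_ms"]),
        onset_b=float(meta["onset_b_ms"]),
        n_baseline=int(meta["n_baseline"]),
    )


def save_stack(path, stack: PunctaStack) -> None:
    """Two-channel stack as TIFF (axes C, Z, Y, X) + YAML voxel metadata + truth CSV."""
    path = Path(path)
    data = np.stack([stack.channel_a, stack.channel_b]).astype(np.float32)
    tifffile.imwrite(path, data)
    path.with_suffix(".yaml").write_text(
        yaml.safe_dump({"voxel_size_um": list(stack.voxel_size), "axes": "CZYX"})
    )
    truth = puncta_table(stack)
    if truth is not None:
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)


def load_stack(path) -> PunctaStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return PunctaStack(
        channel_a=data[0],
        channel_b=data[1],
        voxel_size=tuple(meta["voxel_size_um"]),
    )


def puncta_table(stack: PunctaStack) -> pd.DataFrame | None:
    """Tidy ground-truth table (one row per punctum) from a generated stack."""
    if not stack.truth:
        return None
    rows = []
    for ch in ("a", "b"):
        for r in stack.truth.get(ch, []):
            rows.append(
                {
                    "channel": ch,
                    "x": r["center"][0],
                    "y": r["center"][1],
                    "z": r["center"][2],
                    "volume": r["volume"],
                    "paired": r.get("paired", not r.get("orphan", False)),
                }
            )
    return pd.DataFrame(rows)


def save_abr(path, series: ABRSeries) -> None:
    """Level-by-waveform CSV: first column time (ms), one column per level (dB)."""
    df = pd.DataFrame(
        {"time_ms": series.time}
        | {f"{lvl:g}dB": series.waveforms[i] for i, lvl in enumerate(series.levels)}
    )
    df.to_csv(path, index=False)


def load_abr(path) -> ABRSeries:
    df = pd.read_csv(path)
    levels = np.array([float(c[:-2]) for c in df.columns[1:]])
    return ABRSeries(
        levels=levels,
        time=df["time_ms"].to_numpy(),
        waveforms=df[df.columns[1:]].to_numpy().T,
    )
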