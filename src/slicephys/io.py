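"""File formats: trace tables (delimited text / HDF5), ephys sweep files,
BED-like event interval text, and JSON truth/provenance sidecars."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd

from slicephys.trace import FluorescenceTrace
from slicephys.ephys import RampSweep, RampRecording, CurrentClampRecording
from slicephys.sle import SleEventTrain


PathLike = Union[str, Path]


class FileFormatError(ValueError):
    """Malformed input file."""


# --------------------------------------------------------------------------
# Fluorescence trace tables
# --------------------------------------------------------------------------

def write_traces_csv(path: PathLike, traces: Sequence[FluorescenceTrace],
                     sep: str = "\t") -> None:
    """Delimited table with a ``time_s`` column plus one column per trace."""
    if not traces:
        raise ValueError("no traces to write")
    ref = traces[0]
    data = {"time_s": ref.times}
    for i, tr in enumerate(traces):
        if tr.n_frames != ref.n_frames:
            raise ValueError("all traces in one table must share length")
        data[tr.trace_id or tr.region or f"trace{i}"] = tr.values
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def read_traces_csv(path: PathLike, sep: str = "\t", kind: str = "dff",
                    drug_onset: Optional[float] = None) -> List[FluorescenceTrace]:
    """Read a trace table written by :func:`write_traces_csv`.

    The frame rate is inferred from the ``time_s`` column spacing.
    """
    df = pd.read_csv(path, sep=sep)
    if "time_s" not in df.columns:
        raise FileFormatError(f"{path}: missing required column 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FileFormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
        raise FileFormatError(f"{path}: time_s must be uniformly increasing")
    frame_rate = 1.0 / dt[0]
    traces = []
    for col in df.columns:
        if col == "time_s":
            continue
        traces.append(FluorescenceTrace(
            values=df[col].to_numpy(dtype=float), frame_rate=frame_rate,
            t0=float(t[0]), kind=kind, region=col, trace_id=col,
            drug_onset=drug_onset))
    if not traces:
        raise FileFormatError(f"{path}: no trace columns besides time_s")
    return traces


_TRACE_ATTRS = ("frame_rate", "t0", "kind", "region", "condition",
                "drug_onset", "trace_id")


def write_traces_h5(path: PathLike, traces: Sequence[FluorescenceTrace]) -> None:
    """HDF5 layout: one dataset per trace under ``/traces``, metadata as
    attributes."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("traces")
        for i, tr in enumerate(traces):
            name = tr.trace_id or tr.region or f"trace{i}"
            ds = grp.create_dataset(name, data=tr.values)
            for attr in _TRACE_ATTRS:
                val = getattr(tr, attr)
                if val is not None:
                    ds.attrs[attr] = val


def read_traces_h5(path: PathLike) -> List[FluorescenceTrace]:
    traces = []
    with h5py.File(path, "r") as f:
        if "traces" not in f:
            raise FileFormatError(f"{path}: missing /traces group")
        str_attrs = ("kind", "region", "condition", "trace_id")
        for name in sorted(f["traces"]):
            ds = f["traces"][name]
            kw = {}
            for attr in _TRACE_ATTRS:
                if attr in ds.attrs:
                    val = ds.attrs[attr]
                    kw[attr] = str(val) if attr in str_attrs else float(val)
            kw.setdefault("frame_rate", 10.0)
            kw.setdefault("trace_id", name)
            traces.append(FluorescenceTrace(values=ds[...], **kw))
    return traces


# --------------------------------------------------------------------------
# Event intervals (BED-like text)
# --------------------------------------------------------------------------

def write_events_bed(path: PathLike, trains: Dict[str, SleEventTrain]) -> None:
    """Three-column interval text: ``trace_id  start_s  end_s``."""
    with open(path, "w") as fh:
        fh.write("#trace_id\tstart_s\tend_s\n")
        for tid, train in trains.items():
            for s, e in train.intervals:
                fh.write(f"{tid}\t{s:.3f}\t{e:.3f}\n")


def read_events_bed(path: PathLike) -> Dict[str, List[Tuple[float, float]]]:
    out: Dict[str, List[Tuple[float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tid, s, e = line.split("\t")
            out.setdefault(tid, []).append((float(s), float(e)))
    return out


# --------------------------------------------------------------------------
# Ephys sweeps
# --------------------------------------------------------------------------

def write_ramp_h5(path: PathLike, rec: RampRecording) -> None:
    """Per-sweep groups ``/sweeps/sweep_NNN`` with ``command`` and
    ``current`` datasets and a ``time_from_breakin`` attribute."""
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["recording_type"] = "ramp"
        grp = f.create_group("sweeps")
        for i, sw in enumerate(rec.sweeps):
            g = grp.create_group(f"sweep_{i:03d}")
            g.attrs["time_from_breakin"] = sw.time_from_breakin
            g.create_dataset("command", data=sw.command)
            g.create_dataset("current", data=sw.current)


def read_ramp_h5(path: PathLike) -> RampRecording:
    with h5py.File(path, "r") as f:
        if "sweeps" not in f:
            raise FileFormatError(f"{path}: missing /sweeps group")
        sr = float(f.attrs["sample_rate"])
        sweeps = []
        for name in sorted(f["sweeps"]):
            g = f["sweeps"][name]
            sweeps.append(RampSweep(
                time_from_breakin=float(g.attrs["time_from_breakin"]),
                command=g["command"][...], current=g["current"][...],
                sample_rate=sr))
    return RampRecording(sweeps=sweeps, sample_rate=sr)


def write_ramp_csv(path: PathLike, rec: RampRecording, sep: str = "\t") -> None:
    """Long-format text: sweep index, time from break-in, sample time,
    command (mV), current (pA)."""
    frames = []
    for i, sw in enumerate(rec.sweeps):
        t = np.arange(sw.command.size) / sw.sample_rate
        frames.append(pd.DataFrame({
            "sweep": i, "time_from_breakin_s": sw.time_from_breakin,
            "t_s": t, "command_mv": sw.command, "current_pa": sw.current}))
    pd.concat(frames).to_csv(path, sep=sep, index=False)


def read_ramp_csv(path: PathLike, sep: str = "\t") -> RampRecording:
    df = pd.read_csv(path, sep=sep)
    required = {"sweep", "time_from_breakin_s", "t_s", "command_mv", "current_pa"}
    missing = required - set(df.columns)
    if missing:
        raise FileFormatError(f"{path}: missing columns {sorted(missing)}")
    sweeps = []
    sr = None
    for idx, sub in df.groupby("sweep"):
        t = sub["t_s"].to_numpy(dtype=float)
        sr = 1.0 / (t[1] - t[0])
        sweeps.append(RampSweep(
            time_from_breakin=float(sub["time_from_breakin_s"].iloc[0]),
            command=sub["command_mv"].to_numpy(dtype=float),
            current=sub["current_pa"].to_numpy(dtype=float),
            sample_rate=sr))
    if not sweeps:
        raise FileFormatError(f"{path}: no sweeps")
    return RampRecording(sweeps=sweeps, sample_rate=sr)


def write_cclamp_h5(path: PathLike, rec: CurrentClampRecording) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["pulse_start_s"] = rec.pulse_window[0]
        f.attrs["pulse_end_s"] = rec.pulse_window[1]
        f.attrs["holding_current"] = rec.holding_current
        f.attrs["recording_type"] = "current_clamp"
        grp = f.create_group("sweeps")
        for i, (amp, v) in enumerate(rec.sweeps):
            g = grp.create_group(f"sweep_{i:03d}")
            g.attrs["amplitude_pa"] = amp
            g.create_dataset("voltage", data=v)


def read_cclamp_h5(path: PathLike) -> CurrentClampRecording:
    with h5py.File(path, "r") as f:
        if "sweeps" not in f:
            raise FileFormatError(f"{path}: missing /sweeps group")
        sweeps = []
        for name in sorted(f["sweeps"]):
            g = f["sweeps"][name]
            sweeps.append((float(g.attrs["amplitude_pa"]), g["voltage"][...]))
        return CurrentClampRecording(
            sweeps=sweeps, sample_rate=float(f.attrs["sample_rate"]),
            pulse_window=(float(f.attrs["pulse_start_s"]),
                          float(f.attrs["pulse_end_s"])),
            holding_current=float(f.attrs.get("holding_current", 0.0)))


# --------------------------------------------------------------------------
# JSON sidecars
# --------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return f"<callable {getattr(obj, '__name__', 'fn')}>"
    return obj


def write_truth_json(path: PathLike, truth) -> None:
    """Ground-truth sidecar: event intervals, spike times, and the
    generating config (the conductance function is recorded by name only)."""
    doc = {
        "event_intervals": _jsonable(truth.event_intervals),
        "spike_times": _jsonable(truth.spike_times),
        "spike_times_by_amplitude": _jsonable(truth.spike_times_by_amplitude),
        "params": _jsonable(truth.params),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_truth_json(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(path: PathLike, doc: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(doc), fh, indent=1, default=str)
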