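"""Delimited-text readers and writers for the session data model.

Plain CSV/JSON are the canonical interchange formats: spikes as
``(neuron_id, time_s)``, position as ``(t, x_cm, y_cm)``, events as
``(label, start_s, end_s)``, waveform banks as a neuron x sample matrix
with a sampling-rate header, patterns and ground truth as JSON.  Times
are written with microsecond precision; write-then-read is the identity
up to that precision.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assemblies import AssemblyPattern
from .core import PositionTrace, SpikeTrainSet, ThetaCycles

TIME_DECIMALS = 6


def write_spikes(spikes: SpikeTrainSet, path) -> None:
    rows = []
    for nid in spikes.neuron_ids:
        for t in spikes[nid]:
            rows.append((nid, round(float(t), TIME_DECIMALS)))
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    df.to_csv(path, index=False)


def read_spikes(path) -> SpikeTrainSet:
    """Read a two-column (neuron_id, time_s) file; header required.

    Unsorted per-neuron times are sorted with a warning; non-numeric rows
    raise with the offending line number.
    """
    import warnings

    df = pd.read_csv(path, dtype=str)
    expect = ["neuron_id", "time_s"]
    if list(df.columns[:2]) != expect:
        raise ValueError(f"{path}: header must be {expect!r}")
    nid = pd.to_numeric(df["neuron_id"], errors="coerce")
    ts = pd.to_numeric(df["time_s"], errors="coerce")
    bad = nid.isna() | ts.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-numeric value on line {line}")
    trains = {}
    for n, grp in ts.groupby(nid.astype(int)):
        arr = grp.to_numpy(float)
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            warnings.warn(f"{path}: unsorted spike times for neuron {n}; sorting")
            arr = np.sort(arr)
        trains[int(n)] = arr
    return SpikeTrainSet(trains)


def write_position(trace: PositionTrace, path) -> None:
    pd.DataFrame(
        {"t": trace.t.round(TIME_DECIMALS), "x_cm": trace.x, "y_cm": trace.y}
    ).to_csv(path, index=False)


def read_position(path) -> PositionTrace:
    df = pd.read_csv(path)
    return PositionTrace(df["t"].to_numpy(), df["x_cm"].to_numpy(), df["y_cm"].to_numpy())


def write_events(events, path) -> None:
    """``events``: iterable of (label, start_s, end_s)."""
    pd.DataFrame(events, columns=["label", "start_s", "end_s"]).to_csv(
        path, index=False
    )


def read_events(path) -> list:
    df = pd.read_csv(path)
    return [
        (str(r.label), float(r.start_s), float(r.end_s)) for r in df.itertuples()
    ]


def write_cycles(cycles: ThetaCycles, path) -> None:
    pd.DataFrame({"boundary_s": cycles.boundaries.round(TIME_DECIMALS)}).to_csv(
        path, index=False
    )


def read_cycles(path) -> ThetaCycles:
    return ThetaCycles(pd.read_csv(path)["boundary_s"].to_numpy())


def write_waveform_bank(bank: dict, fs_hz: float, path) -> None:
    """Neuron x sample matrix, sampling rate recorded in the header line."""
    ids = sorted(bank)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={fs_hz}\n")
        for nid in ids:
            fh.write(",".join([str(nid)] + [f"{v:.6g}" for v in bank[nid]]) + "\n")


def read_waveform_bank(path):
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs_hz="):
            raise ValueError(f"{path}: missing sampling-rate header")
        fs = float(header.split("=", 1)[1])
        bank = {}
        for line in fh:
            parts = line.strip().split(",")
            bank[int(parts[0])] = np.asarray(parts[1:], float)
    return bank, fs


def write_patterns(patterns, path) -> None:
    payload = [
        {"neuron_ids": p.neuron_ids, "weights": p.w.tolist()} for p in patterns
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_patterns(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [AssemblyPattern(d["weights"], d["neuron_ids"]) for d in payload]


def write_activation_trace(trace, path) -> None:
    pd.DataFrame({"t": trace.times, "A": trace.strength}).to_csv(path, index=False)


def write_correlogram(ccg, path) -> None:
    cols = {"lag_ms": ccg.lag_centers_ms, "probability": ccg.probability}
    if ccg.band_low is not None:
        cols["band_lo"] = ccg.band_low
        cols["band_hi"] = ccg.band_high
    pd.DataFrame(cols).to_csv(path, index=False)
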