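"""Readers and writers for traces, event tables, reports and grids.

Traces travel either as delimited text with a ``# key: value`` header block
(small fixtures, inspectable) or as ``.npz`` archives with a JSON metadata
entry (long recordings). Event tables are tab-separated text with the
effective duration and excluded intervals in the header. Reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import EVENT_COLUMNS, EventTable
from .errors import InvalidParameterError
from .simulate import IonTrace
from .uncertainty import PoolingGrid

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "write_report",
    "write_grid",
]

_TRACE_MAGIC = "poreqc-trace v1"
_EVENTS_MAGIC = "poreqc-events v1"


def write_trace(path: str | Path, trace: IonTrace) -> None:
    """Write a trace; ``.npz`` gives a compact binary, anything else text."""
    path = Path(path)
    meta = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "bias_voltage_mV": trace.bias_voltage_mV,
        "pore_id": trace.pore_id,
    }
    if path.suffix == ".npz":
        np.savez_compressed(path, samples=trace.samples, meta=json.dumps(meta))
        return
    with open(path, "w") as fh:
        fh.write(f"# {_TRACE_MAGIC}\n")
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("current_pA\n")
        np.savetxt(fh, trace.samples, fmt="%.6f")


def _read_header(path: Path, magic: str) -> dict:
    meta = {}
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# {magic}":
            raise InvalidParameterError(f"{path}: not a {magic} file")
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
    return meta


def read_trace(path: str | Path) -> IonTrace:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as archive:
            meta = json.loads(str(archive["meta"]))
            samples = archive["samples"]
    else:
        meta = _read_header(path, _TRACE_MAGIC)
        samples = np.loadtxt(path, comments="#", skiprows=len(meta) + 2)
    return IonTrace(
        samples=np.asarray(samples, dtype=float),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        bias_voltage_mV=float(meta["bias_voltage_mV"]),
        pore_id=str(meta["pore_id"]),
    )


def write_events(path: str | Path, table: EventTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_EVENTS_MAGIC}\n")
        fh.write(f"# effective_duration_s: {table.effective_duration_s!r}\n")
        fh.write(f"# excluded_intervals: {json.dumps([list(iv) for iv in table.excluded_intervals])}\n")
        table.events[EVENT_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    meta = _read_header(path, _EVENTS_MAGIC)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"pore_id": str, "chunk_id": str})
    df["pore_id"] = df["pore_id"].fillna("")
    df["chunk_id"] = df["chunk_id"].fillna("")
    return EventTable(
        events=df,
        effective_duration_s=float(meta["effective_duration_s"]),
        excluded_intervals=[tuple(iv) for iv in json.loads(meta["excluded_intervals"])],
    )


def write_report(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_grid(prefix: str | Path, grid: PoolingGrid) -> list[Path]:
    """Write a pooling grid as two delimited matrices plus a long table.

    Returns the written paths (``<prefix>_cv_concentration.tsv``,
    ``<prefix>_cv_percent.tsv``, ``<prefix>_long.tsv``).
    """
    prefix = Path(prefix)
    paths = []
    for name, mat in (
        ("cv_concentration", grid.cv_concentration),
        ("cv_percent", grid.cv_percent),
    ):
        df = pd.DataFrame(
            mat,
            index=pd.Index(grid.pore_counts, name="pores"),
            columns=[f"{t:g}min" for t in grid.durations_min],
        )
        p = prefix.parent / f"{prefix.name}_{name}.tsv"
        df.to_csv(p, sep="\t", float_format="%.4f")
        paths.append(p)
    p = prefix.parent / f"{prefix.name}_long.tsv"
    grid.to_frame().to_csv(p, sep="\t", index=False, float_format="%.4f")
    paths.append(p)
    return paths
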