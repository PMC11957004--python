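"""Measurement-uncertainty analysis: pooling pores and acquisition time.

Rebuilds the multi-pore / multi-duration design: each pore records in fixed
(e.g. 5-minute) chunks for a total session (e.g. 90 minutes); for every
combination of pore count P and acquisition time T the chunked store is
assembled into n disjoint pooled replicates, the full mixture + quantification
pipeline runs on each, and the spread across replicates is summarised as

    %CV = 100 * sd / mean

for both QC metrics, yielding a (pores x durations) heatmap grid.
Replicates are disjoint blocks of consecutive chunks (physical repeat
measurements), not bootstrap resamples; a seeded shuffle mode exists for
sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .detect import EventTable
from .errors import ChunkShortageError, FitFailureError, InvalidParameterError
from .quantify import QCReport

__all__ = ["ChunkStore", "PoolingGrid", "chunk_events", "assemble_replicates", "cv_grid"]


@dataclass
class ChunkStore:
    """Per-pore event tables partitioned into consecutive equal chunks."""

    chunk_length_min: float
    chunks: dict[str, list[EventTable]]

    @property
    def pore_ids(self) -> list[str]:
        return sorted(self.chunks)

    def n_chunks(self, pore_id: str) -> int:
        return len(self.chunks[pore_id])


def _interval_overlap(a0: float, a1: float, intervals) -> float:
    return sum(max(0.0, min(a1, e) - max(a0, s)) for s, e in intervals)


def chunk_events(
    tables: Mapping[str, EventTable], chunk_length_min: float
) -> ChunkStore:
    """Partition each pore's recording into consecutive fixed-length chunks.

    Events are assigned by start time into half-open windows
    [c*L, (c+1)*L) — a boundary event belongs to the later chunk. Each chunk
    carries its own effective duration (chunk length minus any excluded
    interval overlap). A trailing partial chunk is dropped.
    """
    if not chunk_length_min > 0:
        raise InvalidParameterError("chunk_length_min must be > 0")
    length_s = chunk_length_min * 60.0
    store: dict[str, list[EventTable]] = {}
    for pore_id, table in tables.items():
        recorded = table.recorded_duration_s
        n_chunks = int(math.floor(recorded / length_s + 1e-9))
        if n_chunks < 1:
            raise InvalidParameterError(
                f"pore {pore_id!r}: recording ({recorded:.0f} s) shorter than one "
                f"{chunk_length_min} min chunk"
            )
        df = table.events
        idx = np.floor(df["start_time_s"].to_numpy(dtype=float) / length_s).astype(int)
        chunks = []
        for c in range(n_chunks):
            sub = df.loc[idx == c].copy()
            sub["chunk_id"] = f"{pore_id}:{c}"
            lo, hi = c * length_s, (c + 1) * length_s
            excl = [
                (max(lo, s), min(hi, e))
                for s, e in table.excluded_intervals
                if s < hi and e > lo
            ]
            effective = length_s - _interval_overlap(lo, hi, table.excluded_intervals)
            chunks.append(EventTable(sub.reset_index(drop=True), effective, excl))
        store[pore_id] = chunks
    return ChunkStore(chunk_length_min=chunk_length_min, chunks=store)


def assemble_replicates(
    store: ChunkStore,
    n_pores: int,
    duration_min: float,
    n_replicates: int = 3,
    seed: int | None = None,
    shuffle: bool = False,
) -> list[EventTable]:
    """Build disjoint pooled replicates for one (pores, duration) combination.

    Each replicate pools ``duration_min / chunk_length`` consecutive unused
    chunks from each of the first ``n_pores`` pores (recording order;
    ``shuffle=True`` draws a seeded permutation of each pore's chunks
    instead). Pooled effective duration is the sum over all chunks used.
    """
    m = duration_min / store.chunk_length_min
    if abs(m - round(m)) > 1e-9:
        raise InvalidParameterError("duration_min must be a multiple of the chunk length")
    m = int(round(m))
    pores = store.pore_ids
    if n_pores > len(pores):
        raise ChunkShortageError(f"requested {n_pores} pores, store has {len(pores)}")
    needed = n_replicates * m
    rng = np.random.default_rng(seed)
    per_pore: dict[str, list[EventTable]] = {}
    for pore_id in pores[:n_pores]:
        chunks = store.chunks[pore_id]
        if len(chunks) < needed:
            raise ChunkShortageError(
                f"combination (pores={n_pores}, duration={duration_min} min): pore "
                f"{pore_id!r} has {len(chunks)} chunks, needs {needed} for "
                f"{n_replicates} disjoint replicates"
            )
        order = list(rng.permutation(len(chunks))) if shuffle else list(range(len(chunks)))
        per_pore[pore_id] = [chunks[i] for i in order]
    replicates = []
    for r in range(n_replicates):
        parts = [per_pore[p][r * m : (r + 1) * m] for p in pores[:n_pores]]
        replicates.append(EventTable.pool([c for block in parts for c in block]))
    return replicates


@dataclass
class PoolingGrid:
    """%CV of both QC metrics over the (pore count x duration) design."""

    pore_counts: list[int]
    durations_min: list[float]
    cv_concentration: np.ndarray  # %, shape (pores, durations); NaN = missing
    cv_percent: np.ndarray
    n_replicates: int
    replicate_values: dict = field(default_factory=dict)

    def cell(self, n_pores: int, duration_min: float) -> tuple[float, float]:
        i = self.pore_counts.index(n_pores)
        j = self.durations_min.index(duration_min)
        return float(self.cv_concentration[i, j]), float(self.cv_percent[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: pores, minutes, metric, cv_percent."""
        rows = []
        for i, p in enumerate(self.pore_counts):
            for j, t in enumerate(self.durations_min):
                rows.append((p, t, "concentration", self.cv_concentration[i, j]))
                rows.append((p, t, "percent_target", self.cv_percent[i, j]))
        return pd.DataFrame(rows, columns=["pores", "minutes", "metric", "cv_percent"])


def _cv(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean == 0.0:
        return float("nan")
    return 100.0 * float(np.std(values, ddof=1)) / mean


def cv_grid(
    store: ChunkStore,
    pore_counts: list[int],
    durations_min: list[float],
    qc_fn: Callable[[EventTable], QCReport],
    n_replicates: int = 3,
    seed: int | None = None,
    shuffle: bool = False,
) -> PoolingGrid:
    """Run the pipeline over every (pores, duration) combination.

    ``qc_fn`` maps a pooled EventTable to a QCReport (typically a closure
    over :func:`poreqc.pipeline.qc_from_event_table` with a fixed config).
    A replicate whose mixture fit fails marks its cell missing (NaN) rather
    than aborting the grid.
    """
    shape = (len(pore_counts), len(durations_min))
    cv_c = np.full(shape, np.nan)
    cv_p = np.full(shape, np.nan)
    values: dict = {}
    for i, n_pores in enumerate(pore_counts):
        for j, dur in enumerate(durations_min):
            reps = assemble_replicates(
                store, n_pores, dur, n_replicates=n_replicates, seed=seed, shuffle=shuffle
            )
            try:
                reports = [qc_fn(rep) for rep in reps]
            except FitFailureError:
                continue
            cs = np.array([r.c_target_pM for r in reports])
            ps = np.array([r.percent_target for r in reports])
            cv_c[i, j] = _cv(cs)
            cv_p[i, j] = _cv(ps)
            values[(n_pores, dur)] = {
                "c_target_pM": cs.tolist(),
                "percent_target": ps.tolist(),
            }
    return PoolingGrid(
        pore_counts=list(pore_counts),
        durations_min=list(durations_min),
        cv_concentration=cv_c,
        cv_percent=cv_p,
        n_replicates=n_replicates,
        replicate_values=values,
    )
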