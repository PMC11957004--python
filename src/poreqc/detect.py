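"""Translocation event extraction from ionic current traces.

A two-pass robust baseline (running median excluding candidate event samples,
noise sd from 1.4826x the median absolute deviation of event-free samples)
feeds a hysteresis threshold detector: an event opens when the current drops
below ``baseline - k_sigma * noise_sd`` and closes when it recovers above
``baseline - noise_sd``. The blockage amplitude is baseline minus the deepest
excursion inside the event — robust for short, filter-attenuated pulses.

Prolonged blockades (pore clogging) are reclassified as excluded intervals;
downstream frequencies are computed over the effective (unclogged) duration
so that timed clogging does not bias concentration estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedFrequencyError
from .simulate import IonTrace

__all__ = [
    "BaselineModel",
    "Event",
    "EventTable",
    "estimate_baseline",
    "detect_events",
    "flag_clogs",
    "event_frequency",
    "extract_events",
]

EVENT_COLUMNS = ["pore_id", "chunk_id", "start_time_s", "dwell_s", "amplitude_pA"]


@dataclass
class BaselineModel:
    """Running baseline estimate and global noise level for one trace."""

    window: int
    baseline: np.ndarray  # pA, same length as the trace
    noise_sd: float  # pA
    degenerate: bool = False  # True when the trace had no measurable noise


@dataclass(frozen=True)
class Event:
    start_time_s: float
    dwell_s: float
    amplitude_pA: float
    pore_id: str = ""
    chunk_id: str = ""

    def __post_init__(self) -> None:
        if not self.dwell_s > 0:
            raise InvalidParameterError("dwell_s must be > 0")
        if not self.amplitude_pA > 0:
            raise InvalidParameterError("amplitude_pA must be > 0")


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pore_id": pd.Series(dtype=str),
            "chunk_id": pd.Series(dtype=str),
            "start_time_s": pd.Series(dtype=float),
            "dwell_s": pd.Series(dtype=float),
            "amplitude_pA": pd.Series(dtype=float),
        }
    )


@dataclass
class EventTable:
    """Detected events plus the effective recording duration.

    ``effective_duration_s`` equals the recorded duration minus the summed
    lengths of excluded (clogged) intervals; it is the denominator of every
    event frequency so that clogging is compensated by construction.
    """

    events: pd.DataFrame = field(default_factory=_empty_frame)
    effective_duration_s: float = 0.0
    excluded_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.effective_duration_s < 0:
            raise InvalidParameterError("effective_duration_s must be >= 0")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise InvalidParameterError(f"event table missing columns: {missing}")

    @classmethod
    def from_events(
        cls,
        events: list[Event],
        effective_duration_s: float,
        excluded_intervals: list[tuple[float, float]] | None = None,
    ) -> "EventTable":
        df = (
            pd.DataFrame(
                {
                    "pore_id": [e.pore_id for e in events],
                    "chunk_id": [e.chunk_id for e in events],
                    "start_time_s": [e.start_time_s for e in events],
                    "dwell_s": [e.dwell_s for e in events],
                    "amplitude_pA": [e.amplitude_pA for e in events],
                }
            )
            if events
            else _empty_frame()
        )
        return cls(df, effective_duration_s, list(excluded_intervals or []))

    @classmethod
    def pool(cls, tables: list["EventTable"]) -> "EventTable":
        """Concatenate tables; effective durations add (disjoint recordings)."""
        frames = [t.events for t in tables if len(t.events)]
        df = pd.concat(frames, ignore_index=True) if frames else _empty_frame()
        return cls(
            df,
            sum(t.effective_duration_s for t in tables),
            [iv for t in tables for iv in t.excluded_intervals],
        )

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def recorded_duration_s(self) -> float:
        return self.effective_duration_s + sum(e - s for s, e in self.excluded_intervals)

    def amplitudes(self) -> np.ndarray:
        return self.events["amplitude_pA"].to_numpy(dtype=float)


def _runs(mask: np.ndarray) -> np.ndarray:
    """(start, stop) index pairs of True runs, stop exclusive."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges.reshape(-1, 2)


def estimate_baseline(trace: IonTrace, window: int = 2001) -> BaselineModel:
    """Two-pass robust baseline for a current trace.

    Pass 1 flags candidate event samples against the global median with a
    5-MAD threshold; pass 2 takes a centred running median over the remaining
    samples (gaps interpolated). The noise sd is the MAD-based robust sd of
    event-free residuals. A trace with no measurable noise gets a machine-
    epsilon floor and the ``degenerate`` flag.
    """
    if window < 3:
        raise InvalidParameterError("window must be >= 3")
    x = np.asarray(trace.samples, dtype=float)
    if len(x) < window:
        raise InvalidParameterError("trace shorter than the baseline window")
    med = float(np.median(x))
    mad_sd = 1.4826 * float(np.median(np.abs(x - med)))
    floor = float(np.finfo(float).eps) * max(1.0, abs(med))
    degenerate = mad_sd < floor
    guard = max(mad_sd, floor)
    candidate = x < med - 5.0 * guard
    masked = np.where(candidate, np.nan, x)
    base = (
        pd.Series(masked)
        .rolling(window, center=True, min_periods=1)
        .median()
        .interpolate(limit_direction="both")
        .to_numpy()
    )
    free = ~candidate
    resid = x[free] - base[free]
    sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if sd < floor:
        sd = floor
        degenerate = True
    return BaselineModel(window=window, baseline=base, noise_sd=sd, degenerate=degenerate)


def _excursion_runs(trace: IonTrace, baseline: BaselineModel) -> np.ndarray:
    x = np.asarray(trace.samples, dtype=float)
    below_close = x < baseline.baseline - baseline.noise_sd
    return _runs(below_close)


def flag_clogs(
    trace: IonTrace, baseline: BaselineModel, max_block_duration_s: float = 1.0
) -> list[tuple[float, float]]:
    """Sub-baseline excursions longer than ``max_block_duration_s`` (clogs).

    Returned intervals are in seconds and should be excluded from the
    effective duration; translocation events never approach this length.
    """
    fs = trace.sampling_rate_hz
    out = []
    for i0, i1 in _excursion_runs(trace, baseline):
        if (i1 - i0) / fs > max_block_duration_s:
            out.append((i0 / fs, i1 / fs))
    return out


def _overlaps(start: float, end: float, intervals) -> bool:
    return any(start < e and end > s for s, e in intervals)


def detect_events(
    trace: IonTrace,
    baseline: BaselineModel,
    k_sigma: float = 5.0,
    min_dwell_s: float = 1.0e-4,
    excluded_intervals: list[tuple[float, float]] | None = None,
) -> EventTable:
    """Hysteresis threshold detection of translocation events.

    An event opens when the current first drops below
    ``baseline - k_sigma * noise_sd`` and closes when it recovers above
    ``baseline - noise_sd``. Amplitude is baseline minus the minimum current
    inside the event. Events shorter than ``min_dwell_s`` or intersecting an
    excluded interval are discarded. Raising ``k_sigma`` can only reduce the
    event count.
    """
    excluded = list(excluded_intervals or [])
    x = np.asarray(trace.samples, dtype=float)
    fs = trace.sampling_rate_hz
    open_thresh = baseline.baseline - k_sigma * baseline.noise_sd
    events: list[Event] = []
    for i0, i1 in _excursion_runs(trace, baseline):
        seg = x[i0:i1]
        deep = np.flatnonzero(seg < open_thresh[i0:i1])
        if len(deep) == 0:
            continue
        start_idx = i0 + int(deep[0])
        start_s, end_s = start_idx / fs, i1 / fs
        dwell = end_s - start_s
        if dwell < min_dwell_s:
            continue
        if _overlaps(start_s, end_s, excluded):
            continue
        i_min = i0 + int(np.argmin(seg))
        amp = float(baseline.baseline[i_min] - x[i_min])
        events.append(Event(start_s, dwell, amp, pore_id=trace.pore_id))
    events.sort(key=lambda e: e.start_time_s)
    effective = trace.duration_s - sum(e - s for s, e in excluded)
    return EventTable.from_events(events, effective, excluded)


def extract_events(
    trace: IonTrace,
    window: int = 2001,
    k_sigma: float = 5.0,
    min_dwell_s: float = 1.0e-4,
    max_block_duration_s: float = 1.0,
) -> EventTable:
    """Full detection pass: baseline, clog exclusion, hysteresis detection."""
    baseline = estimate_baseline(trace, window=window)
    clogs = flag_clogs(trace, baseline, max_block_duration_s=max_block_duration_s)
    return detect_events(
        trace, baseline, k_sigma=k_sigma, min_dwell_s=min_dwell_s, excluded_intervals=clogs
    )


def event_frequency(table: EventTable, subset: pd.Series | np.ndarray | None = None) -> float:
    """Event frequency (events/s) over the effective duration.

    ``subset`` is an optional boolean mask over the table's rows (e.g. a
    species assignment); by default all events count.
    """
    if not table.effective_duration_s > 0:
        raise UndefinedFrequencyError("effective duration is zero; frequency undefined")
    if subset is None:
        count = table.n_events
    else:
        count = int(np.asarray(subset, dtype=bool).sum())
    return count / table.effective_duration_s
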