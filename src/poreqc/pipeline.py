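"""End-to-end QC pipeline glue: events -> mixture -> frequencies -> metrics.

Two entry paths produce the same :class:`~poreqc.quantify.QCReport`:

* the trace path (``qc_from_trace``): baseline + hysteresis detection on a
  rendered or recorded current trace, then mixture fitting and quantification;
* the event path (``qc_from_event_table``): starts from an existing event
  table — either detector output or the simulator's ground-truth stream via
  :func:`event_table_from_truth` — which is how desk-scale surrogates of
  multi-pore, multi-hour experiments are run without rendering hours of
  100 kHz samples.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .detect import EventTable, extract_events
from .geometry import amplitude_scale
from .mixture import MixtureFit, fit_mixture, label_components, select_components, species_frequencies
from .quantify import QCReport, back_calculate_plasma, estimate_concentration, estimate_percent_target
from .simulate import IonTrace, SimSpec, TruthEvent, simulate_events

__all__ = [
    "event_table_from_truth",
    "simulate_event_table",
    "fit_amplitudes",
    "qc_from_event_table",
    "qc_from_trace",
    "marker_hint_for_pore",
]


def event_table_from_truth(
    events: list[TruthEvent],
    duration_s: float,
    clog_intervals=(),
    pore_id: str = "sim",
) -> EventTable:
    """Ground-truth event stream as an EventTable (detection-free path)."""
    import pandas as pd

    if events:
        df = pd.DataFrame(
            {
                "pore_id": pore_id,
                "chunk_id": "",
                "start_time_s": [e.time_s for e in events],
                "dwell_s": [e.dwell_s for e in events],
                "amplitude_pA": [e.amplitude_pA for e in events],
            }
        )
    else:
        df = EventTable().events
    excluded = [tuple(iv) for iv in clog_intervals]
    effective = duration_s - sum(e - s for s, e in excluded)
    return EventTable(df, effective, excluded)


def simulate_event_table(spec: SimSpec, pore_id: str = "sim") -> EventTable:
    """Simulate a recording at event level and package it as an EventTable."""
    events = simulate_events(spec)
    return event_table_from_truth(events, spec.duration_s, spec.clog_intervals, pore_id)


def marker_hint_for_pore(
    config: RunConfig, d_tip_nm: float | None = None
) -> float | None:
    """Expected marker blockade amplitude for a pore, from config knowledge.

    Uses the explicit hint if set; otherwise, when a simulation spec and pore
    diameter are available, scales the simulated marker amplitude to the pore.
    """
    if config.marker_amplitude_hint_pA is not None:
        return config.marker_amplitude_hint_pA
    if config.simulation is not None and d_tip_nm is not None:
        for sp in config.simulation.species:
            if sp.name == "marker":
                return sp.amplitude_mean_pA * amplitude_scale(
                    d_tip_nm, config.simulation.d_ref_nm
                )
    return None


def fit_amplitudes(
    amplitudes: np.ndarray,
    config: RunConfig,
    marker_hint_pA: float | None = None,
) -> MixtureFit:
    """Fit and label the amplitude mixture according to the run config."""
    m = config.mixture
    if m.n_components is not None:
        fit = fit_mixture(amplitudes, m.n_components, seed=m.seed, n_init=m.n_init)
    else:
        fit = select_components(amplitudes, k_max=m.k_max, seed=m.seed, n_init=m.n_init)
    hint = marker_hint_pA if marker_hint_pA is not None else config.marker_amplitude_hint_pA
    return label_components(fit, marker_amplitude_hint_pA=hint)


def qc_from_event_table(
    table: EventTable,
    config: RunConfig,
    marker_hint_pA: float | None = None,
) -> tuple[QCReport, MixtureFit]:
    """Mixture fit + quantification for one (possibly pooled) event table."""
    fit = fit_amplitudes(table.amplitudes(), config, marker_hint_pA)
    freqs = species_frequencies(fit, table)
    c_target = estimate_concentration(freqs, config.marker_concentration_pM)
    percent = estimate_percent_target(freqs)
    plasma = back_calculate_plasma(
        c_target,
        config.target_length_bp,
        config.plasma.dilution_factor,
        config.plasma.elution_volume_uL,
        config.plasma.plasma_volume_mL,
        mass_per_bp=config.mass_per_bp_g_per_mol,
        recovery_fraction=config.plasma.recovery_fraction,
    )
    report = QCReport(
        c_target_pM=c_target,
        percent_target=percent,
        c_marker_nominal_pM=config.marker_concentration_pM,
        fragment_length_bp=config.target_length_bp,
        plasma_equivalent_ng_mL=plasma,
        dilution_factor=config.plasma.dilution_factor,
        elution_volume_uL=config.plasma.elution_volume_uL,
        plasma_volume_mL=config.plasma.plasma_volume_mL,
        frequencies=freqs,
        n_events=table.n_events,
        effective_duration_s=table.effective_duration_s,
        diagnostics={
            "n_components": fit.n_components,
            "bic": fit.bic,
            "converged": fit.converged,
            "excluded_intervals": list(table.excluded_intervals),
        },
    )
    return report, fit


def qc_from_trace(
    trace: IonTrace,
    config: RunConfig,
    marker_hint_pA: float | None = None,
) -> tuple[QCReport, MixtureFit, EventTable]:
    """Full pipeline on a current trace: detect, fit, quantify."""
    d = config.detection
    table = extract_events(
        trace,
        window=d.window,
        k_sigma=d.k_sigma,
        min_dwell_s=d.min_dwell_s,
        max_block_duration_s=d.max_block_duration_s,
    )
    report, fit = qc_from_event_table(table, config, marker_hint_pA)
    return report, fit, table
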