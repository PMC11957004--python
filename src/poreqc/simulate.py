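"""Synthetic ionic current-time traces and translocation event streams.

Emulates the acquisition regime of a glass-nanopore cfDNA QC measurement:
three co-translocating dsDNA species (a short cfDNA-like target, a 1 kbp
internal marker, a high-molecular-weight genomic contaminant) captured in the
diffusion-limited regime, where each species arrives as an independent
homogeneous Poisson process with rate

    lambda_i = capture_rate_constant * concentration_i      [events/s]

i.e. length-independent but concentration-proportional capture. Blockage
amplitudes are Gaussian per species (scaled by the pore-diameter factor
``amplitude_scale``), dwell times log-normal. The continuous-trace renderer
subtracts rectangular pulses from the open-pore current, applies a 4-pole
Bessel low-pass approximating the recording filter, and adds white noise.

All magnitudes not fixed by the assay design (amplitude means/sds, dwell
statistics, open-pore current, noise) are synthetic fixture values chosen to
be realistic for ~10 nm glass pores in 4 M LiCl; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import InvalidParameterError
from .geometry import PoreGeometry, amplitude_scale

__all__ = [
    "SpeciesSpec",
    "SimSpec",
    "IonTrace",
    "TruthEvent",
    "default_mock_species",
    "simulate_events",
    "render_trace",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """One DNA species in the measurement mix.

    ``amplitude_mean_pA``/``amplitude_sd_pA`` describe the blockade-amplitude
    distribution at the reference pore diameter; the mean is rescaled by
    ``amplitude_scale`` for the simulated pore. Dwells are log-normal with the
    given log-space parameters (log-seconds).
    """

    name: str
    length_bp: int
    concentration_pM: float
    amplitude_mean_pA: float
    amplitude_sd_pA: float
    dwell_log_mean: float
    dwell_log_sd: float

    def __post_init__(self) -> None:
        if self.concentration_pM < 0:
            raise InvalidParameterError("concentration_pM must be >= 0")
        if not (self.amplitude_mean_pA > 0 and self.amplitude_sd_pA > 0):
            raise InvalidParameterError("amplitude mean and sd must be > 0")
        if self.length_bp <= 0:
            raise InvalidParameterError("length_bp must be > 0")


def default_mock_species(
    target_pM: float = 120.0,
    marker_pM: float = 100.0,
    gdna_pM: float = 100.0,
) -> list[SpeciesSpec]:
    """The standard three-species mock: 150 bp target, 1 kbp marker, 10 kbp gDNA.

    Amplitude and dwell magnitudes are synthetic fixtures at the 10 nm
    reference pore; only the concentrations are assay design values.
    """
    return [
        SpeciesSpec("target", 150, target_pM, 60.0, 5.0, np.log(2.0e-4), 0.4),
        SpeciesSpec("marker", 1000, marker_pM, 150.0, 9.0, np.log(8.0e-4), 0.4),
        SpeciesSpec("gdna", 10_000, gdna_pM, 300.0, 15.0, np.log(4.0e-3), 0.5),
    ]


@dataclass(frozen=True)
class SimSpec:
    """Full description of one simulated recording."""

    species: tuple[SpeciesSpec, ...]
    duration_s: float
    pore: PoreGeometry | None = None
    d_ref_nm: float = 10.0
    open_pore_current_pA: float = 5000.0
    noise_sd_pA: float = 8.0
    sampling_rate_hz: float = 100_000.0
    filter_cutoff_hz: float = 5_000.0
    capture_rate_constant: float = 0.02  # events / s / pM
    clog_intervals: tuple[tuple[float, float], ...] = ()
    clog_level_fraction: float = 0.4  # fraction of open-pore current during a clog
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(
            self, "clog_intervals", tuple(tuple(c) for c in self.clog_intervals)
        )
        if not self.duration_s > 0:
            raise InvalidParameterError("duration_s must be > 0")
        if not self.capture_rate_constant > 0:
            raise InvalidParameterError("capture_rate_constant must be > 0")
        if not self.sampling_rate_hz > 2 * self.filter_cutoff_hz:
            raise InvalidParameterError("sampling_rate_hz must exceed 2x filter_cutoff_hz")
        prev_end = 0.0
        for start, end in sorted(self.clog_intervals):
            if not (0.0 <= start < end <= self.duration_s):
                raise InvalidParameterError("clog intervals must lie within [0, duration]")
            if start < prev_end:
                raise InvalidParameterError("clog intervals must not overlap")
            prev_end = end

    @property
    def amplitude_factor(self) -> float:
        if self.pore is None or self.pore.tip_diameter_nm is None:
            return 1.0
        return amplitude_scale(self.pore.tip_diameter_nm, self.d_ref_nm)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth injected event (time at capture, species identity)."""

    time_s: float
    species: str
    amplitude_pA: float
    dwell_s: float


@dataclass
class IonTrace:
    """A uniformly sampled ionic-current record (pA)."""

    samples: np.ndarray
    sampling_rate_hz: float
    bias_voltage_mV: float = 500.0
    pore_id: str = "sim"
    truth: list[TruthEvent] | None = None
    truth_clogs: tuple[tuple[float, float], ...] = ()

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate_hz


def _in_any_interval(t: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(t.shape, dtype=bool)
    for start, end in intervals:
        mask |= (t >= start) & (t < end)
    return mask


def simulate_events(spec: SimSpec, rng: np.random.Generator | None = None) -> list[TruthEvent]:
    """Draw the ground-truth event stream for a recording.

    Each species is an independent homogeneous Poisson process with rate
    ``capture_rate_constant * concentration``, thinned to zero inside clog
    intervals. Amplitudes are Normal(mean * pore_scale, sd) truncated at zero;
    dwells LogNormal. Deterministic given ``spec.seed`` (or a supplied rng).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    scale = spec.amplitude_factor
    events: list[TruthEvent] = []
    for sp in spec.species:
        lam = spec.capture_rate_constant * sp.concentration_pM
        n = rng.poisson(lam * spec.duration_s)
        if n == 0:
            continue
        times = np.sort(rng.uniform(0.0, spec.duration_s, size=n))
        mean = sp.amplitude_mean_pA * scale
        amps = rng.normal(mean, sp.amplitude_sd_pA, size=n)
        bad = amps <= 0.0
        while bad.any():  # truncation at 0 by redraw
            amps[bad] = rng.normal(mean, sp.amplitude_sd_pA, size=int(bad.sum()))
            bad = amps <= 0.0
        dwells = rng.lognormal(sp.dwell_log_mean, sp.dwell_log_sd, size=n)
        keep = ~_in_any_interval(times, spec.clog_intervals)
        for t, a, d in zip(times[keep], amps[keep], dwells[keep]):
            events.append(TruthEvent(float(t), sp.name, float(a), float(d)))
    events.sort(key=lambda e: e.time_s)
    return events


def _lowpass_sos(cutoff_hz: float, fs_hz: float):
    # 4-pole Bessel-like low pass, -3 dB at the cutoff
    return signal.bessel(4, cutoff_hz, fs=fs_hz, output="sos", norm="mag")


def render_trace(
    spec: SimSpec,
    events: list[TruthEvent] | None = None,
    pore_id: str = "sim",
    apply_filter: bool = True,
) -> IonTrace:
    """Render the continuous current trace for an event stream.

    The ideal trace is the open-pore level minus rectangular pulses
    (depth = amplitude, width = dwell; overlapping pulses sum, as physical
    co-captures would). Clog intervals are rendered as a depressed plateau at
    ``clog_level_fraction`` of the open-pore current. The ideal trace is then
    low-pass filtered (4-pole Bessel at ``filter_cutoff_hz``) and i.i.d.
    Gaussian noise of sd ``noise_sd_pA`` is added.
    """
    if events is None:
        events = simulate_events(spec)
    fs = spec.sampling_rate_hz
    n = spec.n_samples
    x = np.full(n, spec.open_pore_current_pA, dtype=np.float64)
    for ev in events:
        if not 0.0 <= ev.time_s <= spec.duration_s:
            raise InvalidParameterError("event outside the recording window")
        i0 = int(round(ev.time_s * fs))
        i1 = min(n, i0 + max(1, int(round(ev.dwell_s * fs))))
        x[i0:i1] -= ev.amplitude_pA
    for start, end in spec.clog_intervals:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        x[i0:i1] = spec.clog_level_fraction * spec.open_pore_current_pA
    if apply_filter:
        sos = _lowpass_sos(spec.filter_cutoff_hz, fs)
        zi = signal.sosfilt_zi(sos) * x[0]
        x, _ = signal.sosfilt(sos, x, zi=zi)
    if spec.noise_sd_pA > 0:
        noise_rng = np.random.default_rng([spec.seed, 0xA5])
        x = x + noise_rng.normal(0.0, spec.noise_sd_pA, size=n)
    return IonTrace(
        samples=x,
        sampling_rate_hz=fs,
        bias_voltage_mV=spec.pore.bias_voltage_mV if spec.pore is not None else 500.0,
        pore_id=pore_id,
        truth=list(events),
        truth_clogs=spec.clog_intervals,
    )


def with_seed(spec: SimSpec, seed: int) -> SimSpec:
    """Copy of ``spec`` with a different random seed."""
    return replace(spec, seed=int(seed))
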