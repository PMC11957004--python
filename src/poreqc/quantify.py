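"""The QC math core: internal-marker concentration estimation and %cfDNA.

In the diffusion-limited capture regime the per-species event frequency is
proportional to concentration and independent of fragment length, so a 1 kbp
marker spiked at a known concentration C_M calibrates the assay:

    C_T    = C_M * f_T / f_M                (total target concentration)
    %cfDNA = 100 * f_T / (f_T + f_gDNA)     (qualification metric)

Frequencies (events per second of *effective*, unclogged recording) rather
than raw counts make both metrics invariant to timed pore clogging. Unit
conversions map molar concentrations in the measurement buffer back to
mass-per-volume concentrations in the original plasma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidParameterError, MarkerNotDetectedError, UndefinedFrequencyError

__all__ = [
    "FrequencySet",
    "QCReport",
    "estimate_concentration",
    "estimate_percent_target",
    "molar_to_mass_concentration",
    "mass_to_molar_concentration",
    "back_calculate_plasma",
]

#: Average molar mass of one dsDNA base pair, g/mol/bp.
MASS_PER_BP_G_PER_MOL = 650.0


@dataclass(frozen=True)
class FrequencySet:
    """Per-species translocation frequencies, events/s."""

    f_target: float
    f_marker: float
    f_gdna: float

    def __post_init__(self) -> None:
        if min(self.f_target, self.f_marker, self.f_gdna) < 0:
            raise InvalidParameterError("frequencies must be >= 0")

    def scaled(self, factor: float) -> "FrequencySet":
        return FrequencySet(self.f_target * factor, self.f_marker * factor, self.f_gdna * factor)


def estimate_concentration(freqs: FrequencySet, c_marker_pM: float) -> float:
    """Total target concentration C_T = C_M * f_T / f_M, in pM.

    Scale-free in the frequencies: rescaling all of them (e.g. by a changed
    effective duration) leaves C_T unchanged.
    """
    if not c_marker_pM > 0:
        raise InvalidParameterError("marker concentration must be > 0")
    if freqs.f_marker <= 0:
        raise MarkerNotDetectedError(
            "marker frequency is zero: the internal 1 kbp marker was not detected, "
            "so C_T = C_M * f_T / f_M is undefined"
        )
    return c_marker_pM * freqs.f_target / freqs.f_marker


def estimate_percent_target(freqs: FrequencySet) -> float:
    """%cfDNA = 100 * f_T / (f_T + f_gDNA); 100% means no detectable gDNA."""
    denom = freqs.f_target + freqs.f_gdna
    if denom <= 0:
        raise UndefinedFrequencyError(
            "target and gDNA frequencies are both zero; percent-target undefined"
        )
    return 100.0 * freqs.f_target / denom


def molar_to_mass_concentration(
    c_pM: float, length_bp: float, mass_per_bp: float = MASS_PER_BP_G_PER_MOL
) -> float:
    """Convert a molar DNA concentration (pM) to mass concentration (ng/mL).

    ng/mL = pM * length_bp * mass_per_bp * 1e-6, from 1 pM = 1e-12 mol/L and
    1 ng/mL = 1e-6 g/L. E.g. 10 pM of 150 bp dsDNA at 650 g/mol/bp is
    0.975 ng/mL.
    """
    if c_pM < 0:
        raise InvalidParameterError("concentration must be >= 0")
    if not (length_bp > 0 and mass_per_bp > 0):
        raise InvalidParameterError("length and mass per bp must be > 0")
    return c_pM * length_bp * mass_per_bp * 1e-6


def mass_to_molar_concentration(
    c_ng_per_mL: float, length_bp: float, mass_per_bp: float = MASS_PER_BP_G_PER_MOL
) -> float:
    """Inverse of :func:`molar_to_mass_concentration` (ng/mL -> pM)."""
    if c_ng_per_mL < 0:
        raise InvalidParameterError("concentration must be >= 0")
    if not (length_bp > 0 and mass_per_bp > 0):
        raise InvalidParameterError("length and mass per bp must be > 0")
    return c_ng_per_mL * 1e6 / (length_bp * mass_per_bp)


def back_calculate_plasma(
    c_measured_pM: float,
    length_bp: float,
    dilution_factor: float,
    elution_volume_uL: float,
    plasma_volume_mL: float,
    mass_per_bp: float = MASS_PER_BP_G_PER_MOL,
    recovery_fraction: float = 1.0,
) -> float:
    """Plasma-equivalent cfDNA mass concentration (ng/mL).

    Undoes the measurement dilution (eluate -> measurement buffer) and the
    extraction concentration step (plasma_volume mL of plasma eluted into
    elution_volume µL), assuming the given extraction recovery (default 100%).
    """
    if not (dilution_factor > 0 and elution_volume_uL > 0 and plasma_volume_mL > 0):
        raise InvalidParameterError("dilution and volumes must be > 0")
    if not 0 < recovery_fraction <= 1:
        raise InvalidParameterError("recovery_fraction must be in (0, 1]")
    eluate_ng_mL = molar_to_mass_concentration(c_measured_pM, length_bp, mass_per_bp)
    eluate_ng_mL *= dilution_factor
    return eluate_ng_mL * (elution_volume_uL / (plasma_volume_mL * 1000.0)) / recovery_fraction


@dataclass
class QCReport:
    """The two QC metrics plus provenance of how they were computed."""

    c_target_pM: float
    percent_target: float
    c_marker_nominal_pM: float
    fragment_length_bp: float = 150.0
    plasma_equivalent_ng_mL: float | None = None
    dilution_factor: float | None = None
    elution_volume_uL: float | None = None
    plasma_volume_mL: float | None = None
    frequencies: FrequencySet | None = None
    n_events: int | None = None
    effective_duration_s: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c_target_pM < 0:
            raise InvalidParameterError("c_target_pM must be >= 0")
        if not 0.0 <= self.percent_target <= 100.0:
            raise InvalidParameterError("percent_target must lie in [0, 100]")

    def to_dict(self) -> dict:
        out = {
            "c_target_pM": self.c_target_pM,
            "percent_target": self.percent_target,
            "c_marker_nominal_pM": self.c_marker_nominal_pM,
            "fragment_length_bp": self.fragment_length_bp,
            "plasma_equivalent_ng_mL": self.plasma_equivalent_ng_mL,
            "dilution_factor": self.dilution_factor,
            "elution_volume_uL": self.elution_volume_uL,
            "plasma_volume_mL": self.plasma_volume_mL,
            "n_events": self.n_events,
            "effective_duration_s": self.effective_duration_s,
            "diagnostics": self.diagnostics,
        }
        if self.frequencies is not None:
            out["frequencies_per_s"] = {
                "target": self.frequencies.f_target,
                "marker": self.frequencies.f_marker,
                "gdna": self.frequencies.f_gdna,
            }
        return out
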