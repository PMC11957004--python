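"""Structured run configuration for the QC assay.

All knobs of the pipeline live here so a run is reproducible from its config
file alone: assay constants (marker concentration and fragment lengths),
detection thresholds, mixture settings, pore geometry / buffer conductivity,
optional simulator spec and the plasma back-calculation volumes. Configs
round-trip losslessly through YAML and are content-hashed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .geometry import PoreGeometry
from .simulate import SimSpec, SpeciesSpec

__all__ = [
    "DetectionConfig",
    "MixtureConfig",
    "GeometryConfig",
    "SpeciesConfig",
    "SimulationConfig",
    "PlasmaConfig",
    "RunConfig",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class DetectionConfig(_Model):
    k_sigma: float = Field(5.0, gt=0, description="opening threshold, baseline noise sds")
    min_dwell_s: float = Field(1.0e-4, gt=0)
    window: int = Field(2001, ge=3, description="running-median baseline window, samples")
    max_block_duration_s: float = Field(1.0, gt=0, description="clog reclassification cutoff")


class MixtureConfig(_Model):
    n_components: int | None = Field(
        3, ge=1, description="fixed mixture order; None selects by BIC up to k_max"
    )
    k_max: int = Field(4, ge=1)
    n_init: int = Field(10, ge=1)
    seed: int = 0


class GeometryConfig(_Model):
    tip_diameter_nm: float | None = Field(None, gt=0)
    half_cone_angle_deg: float | None = Field(None, gt=0, lt=90)
    taper_length_um: float | None = Field(None, gt=0)
    capillary_bore_um: float = Field(500.0, gt=0)
    conductivity_S_per_m: float = Field(..., gt=0, description="measurement buffer, S/m")
    bias_voltage_mV: float = 500.0

    def to_pore(self) -> PoreGeometry:
        return PoreGeometry(
            tip_diameter_nm=self.tip_diameter_nm,
            conductivity_S_per_m=self.conductivity_S_per_m,
            half_cone_angle_deg=self.half_cone_angle_deg,
            taper_length_um=self.taper_length_um,
            capillary_bore_um=self.capillary_bore_um,
            bias_voltage_mV=self.bias_voltage_mV,
        )


class SpeciesConfig(_Model):
    name: str
    length_bp: int = Field(..., gt=0)
    concentration_pM: float = Field(..., ge=0)
    amplitude_mean_pA: float = Field(..., gt=0)
    amplitude_sd_pA: float = Field(..., gt=0)
    dwell_log_mean: float
    dwell_log_sd: float = Field(..., gt=0)

    def to_species(self) -> SpeciesSpec:
        return SpeciesSpec(**self.model_dump())


class SimulationConfig(_Model):
    species: tuple[SpeciesConfig, ...]
    duration_s: float = Field(..., gt=0)
    d_ref_nm: float = Field(10.0, gt=0)
    open_pore_current_pA: float = Field(5000.0, gt=0)
    noise_sd_pA: float = Field(8.0, ge=0)
    sampling_rate_hz: float = Field(100_000.0, gt=0)
    filter_cutoff_hz: float = Field(5_000.0, gt=0)
    capture_rate_constant: float = Field(0.02, gt=0)
    clog_intervals: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def to_simspec(self, pore: PoreGeometry | None = None) -> SimSpec:
        return SimSpec(
            species=tuple(s.to_species() for s in self.species),
            duration_s=self.duration_s,
            pore=pore,
            d_ref_nm=self.d_ref_nm,
            open_pore_current_pA=self.open_pore_current_pA,
            noise_sd_pA=self.noise_sd_pA,
            sampling_rate_hz=self.sampling_rate_hz,
            filter_cutoff_hz=self.filter_cutoff_hz,
            capture_rate_constant=self.capture_rate_constant,
            clog_intervals=self.clog_intervals,
            seed=self.seed,
        )


class PlasmaConfig(_Model):
    """Back-calculation from measurement buffer to original plasma."""

    dilution_factor: float = Field(40.0, gt=0)
    elution_volume_uL: float = Field(55.0, gt=0)
    plasma_volume_mL: float = Field(1.0, gt=0)
    recovery_fraction: float = Field(1.0, gt=0, le=1)


class RunConfig(_Model):
    marker_concentration_pM: float = Field(100.0, gt=0)
    marker_length_bp: int = Field(1000, gt=0)
    target_length_bp: int = Field(150, gt=0)
    gdna_length_bp: int = Field(10_000, gt=0)
    mass_per_bp_g_per_mol: float = Field(650.0, gt=0)
    marker_amplitude_hint_pA: float | None = Field(
        None, gt=0, description="expected marker blockade amplitude at this pore"
    )
    detection: DetectionConfig = DetectionConfig()
    mixture: MixtureConfig = MixtureConfig()
    geometry: GeometryConfig | None = None
    simulation: SimulationConfig | None = None
    plasma: PlasmaConfig = PlasmaConfig()

    @model_validator(mode="after")
    def _check_geometry(self) -> "RunConfig":
        if self.geometry is not None:
            self.geometry.to_pore()  # raises on inconsistent cone parameters
        return self

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable sha256 of the canonical JSON form (provenance)."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
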