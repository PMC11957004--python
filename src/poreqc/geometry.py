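"""Glass-nanopipette pore geometry: conductance model and diameter estimation.

The pore is modelled as a truncated cone (tip diameter ``d_tip``, base fixed at
the capillary bore) in series with the single-side access resistance of the
tip opening:

    G = [ R_cone + R_access ]^-1
    R_cone   = 4 L / (sigma * pi * d_tip * d_base)
    R_access = 1 / (sigma * d_tip)

with ``sigma`` the buffer conductivity (S/m). Exactly one of the half-cone
angle or the taper length drives the cone; the other is derived from the
capillary bore. Pore diameters are estimated from measured open-pore
conductance (from IV characteristics) by inverting the forward model with a
bracketed root search.

No default buffer conductivity is shipped: the conductivity of the actual
measurement buffer (e.g. 4 M LiCl Tris-EDTA) must be supplied by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .errors import InvalidParameterError, OutOfRangeError

__all__ = [
    "PoreGeometry",
    "conductance_from_geometry",
    "diameter_from_conductance",
    "amplitude_scale",
]

_NM = 1e-9
_UM = 1e-6


@dataclass(frozen=True)
class PoreGeometry:
    """Geometry and electrical context of one glass nanopipette pore.

    Parameters
    ----------
    tip_diameter_nm:
        Pore (tip) diameter in nm. May be ``None`` when the geometry serves
        as a prior for :func:`diameter_from_conductance`.
    conductivity_S_per_m:
        Bulk conductivity of the measurement buffer, S/m. Required.
    half_cone_angle_deg, taper_length_um:
        Exactly one must be given; the other is derived using the capillary
        bore as the cone base.
    capillary_bore_um:
        Inner diameter of the capillary at the shank, µm (cone base).
    bias_voltage_mV:
        Applied bias, mV (metadata; not used by the conductance model).
    """

    tip_diameter_nm: float | None
    conductivity_S_per_m: float
    half_cone_angle_deg: float | None = None
    taper_length_um: float | None = None
    capillary_bore_um: float = 500.0
    bias_voltage_mV: float = 500.0

    def __post_init__(self) -> None:
        if self.tip_diameter_nm is not None and not self.tip_diameter_nm > 0:
            raise InvalidParameterError("tip_diameter_nm must be > 0")
        if not self.conductivity_S_per_m > 0:
            raise InvalidParameterError("conductivity_S_per_m must be > 0")
        if not self.capillary_bore_um > 0:
            raise InvalidParameterError("capillary_bore_um must be > 0")
        given = (self.half_cone_angle_deg is not None, self.taper_length_um is not None)
        if sum(given) != 1:
            raise InvalidParameterError(
                "exactly one of half_cone_angle_deg / taper_length_um must be set"
            )
        if self.half_cone_angle_deg is not None and not 0 < self.half_cone_angle_deg < 90:
            raise InvalidParameterError("half_cone_angle_deg must lie in (0, 90)")
        if self.taper_length_um is not None and not self.taper_length_um > 0:
            raise InvalidParameterError("taper_length_um must be > 0")

    def taper_length_for(self, tip_diameter_nm: float) -> float:
        """Cone length in µm for a given tip diameter (derived if angle-driven)."""
        if self.taper_length_um is not None:
            return self.taper_length_um
        d_base = self.capillary_bore_um * _UM
        d_tip = tip_diameter_nm * _NM
        theta = math.radians(self.half_cone_angle_deg)  # type: ignore[arg-type]
        return max(d_base - d_tip, 0.0) / (2.0 * math.tan(theta)) / _UM

    def derived_half_cone_angle_deg(self, tip_diameter_nm: float) -> float:
        """Half-cone angle in degrees (derived if taper-length-driven)."""
        if self.half_cone_angle_deg is not None:
            return self.half_cone_angle_deg
        d_base = self.capillary_bore_um * _UM
        d_tip = tip_diameter_nm * _NM
        length = self.taper_length_um * _UM  # type: ignore[operator]
        return math.degrees(math.atan((d_base - d_tip) / (2.0 * length)))


def _conductance_nS(d_tip_nm: float, geom: PoreGeometry) -> float:
    d_tip = d_tip_nm * _NM
    d_base = geom.capillary_bore_um * _UM
    length = geom.taper_length_for(d_tip_nm) * _UM
    sigma = geom.conductivity_S_per_m
    r_cone = 4.0 * length / (sigma * math.pi * d_tip * d_base)
    r_access = 1.0 / (sigma * d_tip)
    return 1e9 / (r_cone + r_access)


def conductance_from_geometry(geom: PoreGeometry) -> float:
    """Open-pore conductance in nS for a fully specified geometry.

    Strictly increasing in tip diameter and linear in buffer conductivity.
    """
    if geom.tip_diameter_nm is None:
        raise InvalidParameterError("tip_diameter_nm is required for the forward model")
    return _conductance_nS(geom.tip_diameter_nm, geom)


def diameter_from_conductance(conductance_nS: float, geom_prior: PoreGeometry) -> float:
    """Tip diameter (nm) whose forward-model conductance equals the measured value.

    Parameters
    ----------
    conductance_nS:
        Measured open-pore conductance, nS (slope of the IV characteristic).
    geom_prior:
        Geometry with cone angle (or taper length) and conductivity known;
        its ``tip_diameter_nm`` is ignored.

    Returns
    -------
    float
        The unique diameter in [0.1 nm, 10 µm] solving the forward model,
        found by bracketed root search (Brent), accurate to ~1e-9 relative.
    """
    if not conductance_nS > 0:
        raise InvalidParameterError("conductance must be > 0")
    lo, hi = 0.1, 1e4  # nm
    f = lambda d: _conductance_nS(d, geom_prior) - conductance_nS
    if f(lo) > 0 or f(hi) < 0:
        raise OutOfRangeError(
            f"no pore diameter in [0.1 nm, 10 um] matches G = {conductance_nS} nS"
        )
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-15)


def amplitude_scale(d_tip_nm: float, d_ref_nm: float, exponent: float = 2.0) -> float:
    """Blockage-amplitude scale factor (d_ref/d_tip)**exponent for a pore.

    Wider pores give shallower relative blockades; the default inverse-square
    reflects cross-sectional volume exclusion. Mean blockade amplitudes
    simulated at the reference diameter are multiplied by this factor.
    """
    if not (d_tip_nm > 0 and d_ref_nm > 0):
        raise InvalidParameterError("diameters must be > 0")
    return (d_ref_nm / d_tip_nm) ** exponent


def roundtrip_residual(geom: PoreGeometry) -> float:
    """|d - invert(forward(d))| in nm; diagnostic used by tests and docs."""
    g = conductance_from_geometry(geom)
    d = diameter_from_conductance(g, replace(geom, tip_diameter_nm=None))
    return abs(d - geom.tip_diameter_nm)  # type: ignore[operator]
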