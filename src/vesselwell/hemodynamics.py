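"""Closed-form orbital-shaker wall-shear-stress (WSS) estimation.

A culture plate on an orbital shaker swirls its medium, exposing the cell
layer to a pulsatile shear whose magnitude can be estimated from the
Stokes-second-problem analysis of an oscillating plate:

.. math::

    \\tau_{max} = r_{orb} \\sqrt{\\rho \\mu \\omega^3},

with orbit radius :math:`r_{orb}` (m), medium density :math:`\\rho`
(kg m^-3), dynamic viscosity :math:`\\mu` (Pa s) and angular frequency
:math:`\\omega = 2\\pi\\,\\mathrm{rpm}/60` (rad s^-1).  The estimate is the
cycle-peak shear at the wall far from the well center; published CFD work
on swirled 6-well plates reports radially resolved mean-WSS windows that
this analytical value is checked against (peripheral zone 0.4–1.2 Pa and
central zone 0.3–0.8 Pa at 135 rpm).

The rotation frequency doubles as a heartbeat analogue: each orbit is one
shear pulse, so rpm maps one-to-one onto beats per minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Published mean-WSS windows (Pa) for a swirled 6-well plate at 135 rpm.
PERIPHERY_WSS_RANGE_PA: tuple[float, float] = (0.4, 1.2)
CENTER_WSS_RANGE_PA: tuple[float, float] = (0.3, 0.8)

#: Flow-regime annotations per zone (fixed strings, independent of tau).
PERIPHERY_REGIME = "pulsatile-laminar"
CENTER_REGIME = "disturbed"

#: Default heart-rate bands (bpm): label -> (low, high], used by
#: :func:`rpm_to_beat_equivalent`.
DEFAULT_HEART_RATE_BANDS: dict[str, tuple[float, float]] = {
    "resting": (40.0, 100.0),
    "exercise": (100.0, 200.0),
}


@dataclass(frozen=True)
class ShearModel:
    """Operating parameters of the orbital-shaker shear system (SI units).

    Defaults reproduce the study conditions: 135 rpm on a 9.5 mm-orbit
    shaker, 2 mL of culture medium in a 35 mm well, water-like density and
    a DMEM-like viscosity at 37 °C.
    """

    rpm: float = 135.0
    orbital_radius_m: float = 0.0095
    fluid_density: float = 1000.0  # kg m^-3
    fluid_viscosity: float = 7.8e-4  # Pa s
    well_diameter_m: float = 0.035
    medium_volume_ml: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "orbital_radius_m",
            "fluid_density",
            "fluid_viscosity",
            "well_diameter_m",
            "medium_volume_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rpm < 0:
            raise ValueError("rpm must be non-negative")

    @property
    def omega(self) -> float:
        """Angular frequency (rad/s)."""
        return 2.0 * math.pi * self.rpm / 60.0


def stokes_wss(model: ShearModel) -> float:
    """Cycle-peak wall shear stress (Pa) from the Stokes-layer estimate.

    ``tau = r_orb * sqrt(rho * mu * omega^3)``; exactly zero at rest and
    strictly increasing in every physical parameter.
    """
    return model.orbital_radius_m * math.sqrt(
        model.fluid_density * model.fluid_viscosity * model.omega**3
    )


def zone_shear_summary(model: ShearModel, geom=None) -> dict:
    """Zone-level shear summary for one well.

    Combines the analytical cycle-peak estimate with the published
    zone-resolved mean-WSS windows, and flags whether the analytical value
    falls inside the peripheral window (consistency of the operating point
    with the physiological target range).  ``geom`` (a
    :class:`~vesselwell.geometry.WellGeometry`) is only echoed for context
    — the closed form carries no radial resolution.
    """
    tau = stokes_wss(model)
    summary = {
        "tau_peak_pa": tau,
        "rpm": model.rpm,
        "periphery": {
            "low_pa": PERIPHERY_WSS_RANGE_PA[0],
            "high_pa": PERIPHERY_WSS_RANGE_PA[1],
            "regime": PERIPHERY_REGIME,
        },
        "center": {
            "low_pa": CENTER_WSS_RANGE_PA[0],
            "high_pa": CENTER_WSS_RANGE_PA[1],
            "regime": CENTER_REGIME,
        },
        "periphery_consistent": bool(
            PERIPHERY_WSS_RANGE_PA[0] <= tau <= PERIPHERY_WSS_RANGE_PA[1]
        ),
    }
    if geom is not None:
        summary["well"] = geom.to_dict()
    return summary


def rpm_to_beat_equivalent(
    rpm: float, bands: dict[str, tuple[float, float]] | None = None
) -> tuple[float, str]:
    """Map shaker rpm to its heartbeat-rate equivalent (bpm) with a band label.

    The mapping is the identity (one orbit = one pulse); the label places
    the rate within configurable physiological bands.  Returns
    ``(bpm, band)`` where band is one of the configured band names,
    ``"none"`` for zero, or ``"outside-physiological"``.
    """
    if rpm < 0:
        raise ValueError("rpm must be non-negative")
    if bands is None:
        bands = DEFAULT_HEART_RATE_BANDS
    if rpm == 0:
        return 0.0, "none"
    for name, (low, high) in bands.items():
        if low < rpm <= high or (rpm == low == min(b[0] for b in bands.values())):
            return float(rpm), name
    return float(rpm), "outside-physiological"
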