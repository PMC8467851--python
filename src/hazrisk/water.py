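"""Influence radii and volumes for groundwater, lake and river pollution.

Each water medium gets an advection–dispersion screening model giving the
distance from the spill at which the concentration falls to the medium's
limit value, after an elapsed diffusion time. All radii share the shape

    r = (advection) + (dispersion length) * ln(source term / threshold term)

with the advection term v*t (zero for lakes, which are static), and are
clamped at zero from below: a log argument below 1 means the threshold
concentration is never exceeded beyond the source, where the model is
outside its validity regime.

Volumes: groundwater pollution occupies a hemisphere (2/3)*pi*r^3; surface
water (lake/river) a quarter sphere (1/3)*pi*r^3 when the road runs
alongside the water body and a hemisphere when it crosses it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network import (
    GroundwaterAttributes,
    LakeAttributes,
    ReleaseScenario,
    RiverAttributes,
    RoadSegment,
    StabilityParameters,
)
from .plume import air_pollution_volume

__all__ = [
    "MEDIA",
    "PollutionVolumes",
    "groundwater_radius",
    "groundwater_volume",
    "lake_radius",
    "river_radius",
    "surface_water_volume",
    "pollution_volumes",
]

#: Medium order used throughout: index 0..3.
MEDIA = ("air", "groundwater", "lake", "river")

#: Lateral-dispersion coefficient of the surface-water models (dimensionless).
SURFACE_DISPERSION_COEF = 0.58
#: Transverse mixing coefficient in the river far-bank term (dimensionless).
RIVER_MIXING_COEF = 0.145


@dataclass(frozen=True)
class PollutionVolumes:
    """Per-medium influence radii (m) and volumes (m^3), ordered as
    (air, groundwater, lake, river); absent media carry zeros."""

    radii: tuple[float, float, float, float]
    volumes: tuple[float, float, float, float]
    present: tuple[bool, bool, bool, bool]

    def __post_init__(self) -> None:
        for r, v, p in zip(self.radii, self.volumes, self.present):
            if r < 0 or v < 0:
                raise ValueError("radii and volumes must be >= 0")
            if not p and (r != 0.0 or v != 0.0):
                raise ValueError("absent media must have zero radius and volume")


def groundwater_radius(
    scenario: ReleaseScenario, attrs: GroundwaterAttributes, t: int,
) -> float:
    """Groundwater pollution influence radius (m) at period t.

    r = v(t)*t_G + sqrt(H*u**t_G) * ln( Q / (C_gw * S * sqrt(pi*H*u**t_G)) ),
    clamped at 0; t_G is the elapsed time since release into the aquifer.
    """
    t_g = scenario.elapsed_times_s[0]
    h = attrs.depth
    s = attrs.wet_cross_section
    u = scenario.friction_velocity
    disp = math.sqrt(h * u * t_g)
    arg = scenario.total_amount_mg / (
        scenario.env_thresholds[1] * s * math.sqrt(math.pi * h * u * t_g))
    r = attrs.flow_profile[t] * t_g + disp * math.log(arg)
    return max(0.0, r)


def groundwater_volume(r: float) -> float:
    """Hemispherical groundwater pollution volume (m^3)."""
    if r < 0:
        raise ValueError(f"radius must be >= 0, got {r}")
    return (2.0 / 3.0) * math.pi * r ** 3


def lake_radius(scenario: ReleaseScenario, attrs: LakeAttributes) -> float:
    """Lake pollution influence radius (m); time-of-day independent since
    lake water is static.

    r = sqrt(0.58*H*u**t_L) * ln( Q / (0.58*pi*H^2*u**t_L*C_lake) ), clamped.
    """
    t_l = scenario.elapsed_times_s[1]
    h = attrs.depth
    u = scenario.friction_velocity
    disp = math.sqrt(SURFACE_DISPERSION_COEF * h * u * t_l)
    arg = scenario.total_amount_mg / (
        SURFACE_DISPERSION_COEF * math.pi * h * h * u * t_l
        * scenario.env_thresholds[2])
    return max(0.0, disp * math.log(arg))


def river_radius(
    scenario: ReleaseScenario, attrs: RiverAttributes, t: int,
) -> float:
    """River pollution influence radius (m) at period t.

    Advection by the longitudinal flow plus a dispersion term whose source
    factor (2 + exp(-W^2/(0.145*H*u**t_R))) interpolates between 3 for a
    narrow channel (full far-bank reflection) and 2 for an effectively
    infinite width.
    """
    t_r = scenario.elapsed_times_s[2]
    h = attrs.depth
    u = scenario.friction_velocity
    w = attrs.width
    disp = math.sqrt(SURFACE_DISPERSION_COEF * h * u * t_r)
    bank_factor = 2.0 + math.exp(-(w * w) / (RIVER_MIXING_COEF * h * u * t_r))
    arg = scenario.total_amount_mg * bank_factor / (
        SURFACE_DISPERSION_COEF * math.pi * h * h * u * t_r
        * scenario.env_thresholds[3])
    r = attrs.flow_profile[t] * t_r + disp * math.log(arg)
    return max(0.0, r)


def surface_water_volume(r: float, relation: str) -> float:
    """Surface-water (lake/river) pollution volume (m^3).

    'alongside' — the road runs beside the water body, so only a quarter
    sphere is submerged: (1/3)*pi*r^3. 'crossing' — the road passes over it
    and the full hemisphere counts: (2/3)*pi*r^3.
    """
    if r < 0:
        raise ValueError(f"radius must be >= 0, got {r}")
    if relation == "alongside":
        return (1.0 / 3.0) * math.pi * r ** 3
    if relation == "crossing":
        return (2.0 / 3.0) * math.pi * r ** 3
    raise ValueError(f"relation must be 'alongside' or 'crossing', got {relation!r}")


def pollution_volumes(
    segment: RoadSegment,
    scenario: ReleaseScenario,
    stability: StabilityParameters,
    t: int,
) -> PollutionVolumes:
    """All four media for one segment-period.

    The air volume is always computed (from the period's wind speed); each
    water medium contributes only if the segment carries its attributes.
    """
    r_air, v_air = air_pollution_volume(
        scenario, stability, segment.wind_speed[t])
    radii = [r_air, 0.0, 0.0, 0.0]
    volumes = [v_air, 0.0, 0.0, 0.0]
    present = [True, False, False, False]

    wa = segment.water
    if wa.groundwater is not None:
        r = groundwater_radius(scenario, wa.groundwater, t)
        radii[1], volumes[1], present[1] = r, groundwater_volume(r), True
    if wa.lake is not None:
        r = lake_radius(scenario, wa.lake)
        radii[2] = r
        volumes[2] = surface_water_volume(r, wa.lake.relation)
        present[2] = True
    if wa.river is not None:
        r = river_radius(scenario, wa.river, t)
        radii[3] = r
        volumes[3] = surface_water_volume(r, wa.river.relation)
        present[3] = True

    return PollutionVolumes(
        radii=tuple(radii), volumes=tuple(volumes), present=tuple(present))
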