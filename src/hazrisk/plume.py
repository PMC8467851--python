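"""Gaussian plume dispersion and AEGL threat-zone geometry.

A continuous point release of strength Q^Hazard (mg/s) disperses downwind
with Gaussian crosswind and vertical profiles whose spreads follow power
laws sigma_y = a*x^c, sigma_z = b*x^d (x in metres). Along the centreline,
with source height and off-axis coordinates dropped, the concentration is

    C(x) = Q^Hazard / (pi * a * b * v_wind * x^(c+d))

which inverts in closed form to the radius where a threshold C is reached:

    r(C) = [Q^Hazard / (pi * a * b * v_wind * C)]^(1/(c+d))

The three AEGL thresholds (AEGL-1 < AEGL-2 < AEGL-3) give three nested
radii r_1 >= r_2 >= r_3 partitioning the impact disc into concentric injury
rings; the AEGL-2 radius also bounds the hemispherical air-pollution volume
(2/3)*pi*r^3.
"""

from __future__ import annotations

import math
import csv
from dataclasses import dataclass

from .network import ReleaseScenario, StabilityParameters

__all__ = [
    "ExposureZones",
    "PASQUILL_GIFFORD",
    "load_stability_table",
    "get_stability",
    "plume_concentration_3d",
    "centerline_concentration",
    "exposure_radius",
    "exposure_zones",
    "air_pollution_volume",
]


#: Pasquill–Gifford stability classes A (very unstable) .. F (stable) as
#: power-law fits sigma_y = a*x^0.894, sigma_z = b*x^d with x and sigma in
#: metres. Derived from the classic rural power-law curve fits (originally
#: tabulated for x in km) converted to metre units; the small additive
#: offsets of the original sigma_z fits are dropped, so these are smooth
#: approximations adequate for screening-level assessment.
PASQUILL_GIFFORD: dict[str, StabilityParameters] = {
    "A": StabilityParameters(a=0.4430, b=6.63e-4, c=0.894, d=1.941),
    "B": StabilityParameters(a=0.3244, b=0.03810, c=0.894, d=1.149),
    "C": StabilityParameters(a=0.2163, b=0.11280, c=0.894, d=0.911),
    "D": StabilityParameters(a=0.1414, b=0.22190, c=0.894, d=0.725),
    "E": StabilityParameters(a=0.1050, b=0.21080, c=0.894, d=0.678),
    "F": StabilityParameters(a=0.0707, b=0.08650, c=0.894, d=0.740),
}


def load_stability_table(path: str) -> dict[str, StabilityParameters]:
    """Read a stability-class CSV (class, a, b, c, d) override."""
    out: dict[str, StabilityParameters] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["class"]] = StabilityParameters(
                a=float(row["a"]), b=float(row["b"]),
                c=float(row["c"]), d=float(row["d"]))
    if not out:
        raise ValueError(f"empty stability table: {path}")
    return out


def get_stability(stability_class: str) -> StabilityParameters:
    """Built-in Pasquill–Gifford parameters for class A..F."""
    try:
        return PASQUILL_GIFFORD[stability_class.upper()]
    except KeyError:
        raise KeyError(
            f"unknown stability class {stability_class!r}; "
            f"valid: {', '.join(PASQUILL_GIFFORD)}") from None


@dataclass(frozen=True)
class ExposureZones:
    """The three concentric AEGL rings around a point release.

    ``radii[u]`` (m) is the distance at which the concentration falls to the
    AEGL-(u+1) threshold, so radii are non-increasing (higher threshold,
    smaller radius). ``areas[u]`` (m^2) is the ring between radius u and
    u+1, with the innermost ring a full disc (the convention r_4 = 0).
    """

    radii: tuple[float, float, float]
    areas: tuple[float, float, float]

    def __post_init__(self) -> None:
        r1, r2, r3 = self.radii
        if not (r1 >= r2 >= r3 >= 0.0):
            raise ValueError(f"zone radii must be nested r1 >= r2 >= r3 >= 0: {self.radii}")
        if any(s < 0 for s in self.areas):
            raise ValueError(f"ring areas must be >= 0: {self.areas}")

    @classmethod
    def from_radii(cls, radii: tuple[float, float, float]) -> "ExposureZones":
        r = (*radii, 0.0)
        areas = tuple(math.pi * (r[u] ** 2 - r[u + 1] ** 2) for u in range(3))
        return cls(radii=tuple(radii), areas=areas)

    @property
    def total_area(self) -> float:
        """Area of the outermost disc; equals the sum of the ring areas."""
        return math.pi * self.radii[0] ** 2


def plume_concentration_3d(
    x: float, y: float, z: float,
    scenario: ReleaseScenario,
    stability: StabilityParameters,
    v_wind: float,
) -> float:
    """Full Gaussian plume concentration (mg/m^3) at downwind point (x, y, z).

    Includes the ground-reflection image term for a source at height H.
    Not used in the risk chain (which works with the centreline form), but
    provided for completeness.
    """
    if x <= 0:
        raise ValueError(f"downwind distance x must be > 0, got {x}")
    if v_wind <= 0:
        raise ValueError(f"wind speed must be > 0, got {v_wind}")
    sy = stability.sigma_y(x)
    sz = stability.sigma_z(x)
    h = scenario.source_height_m
    base = scenario.release_rate_mg_s / (math.pi * v_wind * sy * sz)
    crosswind = math.exp(-y * y / (2.0 * sy * sy))
    vertical = (math.exp(-((z - h) ** 2) / (2.0 * sz * sz))
                + math.exp(-((z + h) ** 2) / (2.0 * sz * sz)))
    return base * crosswind * vertical


def centerline_concentration(
    x: float,
    scenario: ReleaseScenario,
    stability: StabilityParameters,
    v_wind: float,
) -> float:
    """Ground-level centreline concentration (mg/m^3) at downwind distance x.

    Strictly decreasing in x; inverse of :func:`exposure_radius`.
    """
    if x <= 0:
        raise ValueError(f"downwind distance x must be > 0, got {x}")
    if v_wind <= 0:
        raise ValueError(f"wind speed must be > 0, got {v_wind}")
    s = stability
    return scenario.release_rate_mg_s / (
        math.pi * s.a * s.b * v_wind * x ** (s.c + s.d))


def exposure_radius(
    c_threshold: float,
    scenario: ReleaseScenario,
    stability: StabilityParameters,
    v_wind: float,
) -> float:
    """Distance (m) at which the centreline concentration equals a threshold.

    Closed-form inversion of :func:`centerline_concentration`; monotone
    decreasing in both the threshold and the wind speed.
    """
    if c_threshold <= 0:
        raise ValueError(f"concentration threshold must be > 0, got {c_threshold}")
    if v_wind <= 0:
        raise ValueError(f"wind speed must be > 0, got {v_wind}")
    s = stability
    bracket = scenario.release_rate_mg_s / (math.pi * s.a * s.b * v_wind * c_threshold)
    return bracket ** (1.0 / (s.c + s.d))


def exposure_zones(
    scenario: ReleaseScenario,
    stability: StabilityParameters,
    v_wind: float,
) -> ExposureZones:
    """AEGL ring radii and areas for one segment-period wind speed."""
    radii = tuple(
        exposure_radius(c, scenario, stability, v_wind)
        for c in scenario.aegl_thresholds)
    # AEGL thresholds increase, so radii decrease: reorder to (r1, r2, r3)
    # is unnecessary — threshold u=1 (lowest) already yields the largest r.
    return ExposureZones.from_radii(radii)


def air_pollution_volume(
    scenario: ReleaseScenario,
    stability: StabilityParameters,
    v_wind: float,
) -> tuple[float, float]:
    """Air-pollution influence radius and hemispherical volume.

    The air concentration limit is the AEGL-2 value; the polluted region is
    the hemisphere of that radius: V = (2/3)*pi*r^3.
    """
    r = exposure_radius(scenario.env_thresholds[0], scenario, stability, v_wind)
    return r, (2.0 / 3.0) * math.pi * r ** 3
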