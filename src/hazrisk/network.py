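"""Road-network data model for time-varying hazmat transport risk assessment.

The unit of assessment is a road segment (an arc between two intersection
nodes) carrying 24-period diurnal profiles of vehicle density, population
density and wind speed, plus optional water-body attributes for groundwater,
lake and river pollution modelling.

Internal unit conventions (enforced on load):

* segment length in km (it enters the probability model and the population
  bearing-capacity denominator through an explicit 10^3 factor);
* all dispersion maths in m, s, mg and mg/m^3;
* population density stored as persons/m^2 — inputs given in persons/km^2
  must be converted with :func:`normalize_population_density`.

Time is a discrete index ``t in {0..23}``, one period per hour of day; no
sub-hour interpolation is performed.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field
from typing import Literal, Mapping

__all__ = [
    "N_PERIODS",
    "NetworkValidationError",
    "TimeProfile",
    "GroundwaterAttributes",
    "LakeAttributes",
    "RiverAttributes",
    "WaterAttributes",
    "RoadSegment",
    "RoadNetwork",
    "ReleaseScenario",
    "StabilityParameters",
    "ROAD_TYPES",
    "LAND_USES",
    "FRICTION_VELOCITY_BOUNDS",
    "normalize_population_density",
    "load_network",
    "save_network",
    "load_scenario",
    "save_scenario",
]

N_PERIODS = 24

ROAD_TYPES = (
    "two-lane",
    "undivided multilane",
    "divided multilane",
    "cycle lane",
    "expressway",
)

LAND_USES = ("residential", "commercial", "school", "mixed")

#: Admissible range for the water-flow friction velocity u* (m/s).
FRICTION_VELOCITY_BOUNDS = (0.02, 0.553)

Relation = Literal["alongside", "crossing"]


class NetworkValidationError(ValueError):
    """Raised when an input violates a structural or physical invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise NetworkValidationError(msg)


@dataclass(frozen=True)
class TimeProfile:
    """A diurnal profile: exactly 24 finite, non-negative values.

    The unit is carried by context (veh/km, persons/m^2, m/s, ...).
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        _require(
            len(vals) == N_PERIODS,
            f"TimeProfile must have exactly {N_PERIODS} entries, got {len(vals)}",
        )
        for t, v in enumerate(vals):
            _require(math.isfinite(v), f"TimeProfile value at period {t} is not finite")
            _require(v >= 0.0, f"TimeProfile value at period {t} is negative: {v}")

    def __getitem__(self, t: int) -> float:
        return self.values[t]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return N_PERIODS

    @classmethod
    def constant(cls, value: float) -> "TimeProfile":
        return cls(values=(float(value),) * N_PERIODS)


@dataclass(frozen=True)
class GroundwaterAttributes:
    """Groundwater body under a segment.

    flow_profile
        average flow velocity v^Gwater(t), m/s.
    depth
        average depth H^Gwater of the aquifer, m (> 0).
    wet_cross_section
        wet cross-sectional area S^Gwater, m^2 (> 0).
    """

    flow_profile: TimeProfile
    depth: float
    wet_cross_section: float

    def __post_init__(self) -> None:
        _require(self.depth > 0, "groundwater depth must be > 0")
        _require(self.wet_cross_section > 0, "groundwater wet cross-section must be > 0")


@dataclass(frozen=True)
class LakeAttributes:
    """Static surface water beside/under a segment; depth in m, relation
    selects the quarter-sphere ('alongside') or hemisphere ('crossing')
    pollution volume."""

    depth: float
    relation: Relation

    def __post_init__(self) -> None:
        _require(self.depth > 0, "lake depth must be > 0")
        _require(self.relation in ("alongside", "crossing"),
                 f"lake relation must be 'alongside' or 'crossing', got {self.relation!r}")


@dataclass(frozen=True)
class RiverAttributes:
    """Dynamic surface water: longitudinal flow profile (m/s), depth (m),
    width (m) and the road/water relation."""

    flow_profile: TimeProfile
    depth: float
    width: float
    relation: Relation

    def __post_init__(self) -> None:
        _require(self.depth > 0, "river depth must be > 0")
        _require(self.width > 0, "river width must be > 0")
        _require(self.relation in ("alongside", "crossing"),
                 f"river relation must be 'alongside' or 'crossing', got {self.relation!r}")


@dataclass(frozen=True)
class WaterAttributes:
    """Optional water bodies attached to a segment; any medium may be absent."""

    groundwater: GroundwaterAttributes | None = None
    lake: LakeAttributes | None = None
    river: RiverAttributes | None = None

    @property
    def any_present(self) -> bool:
        return any(m is not None for m in (self.groundwater, self.lake, self.river))


@dataclass(frozen=True)
class RoadSegment:
    """One arc (i, j) of the network — the unit of assessment.

    Segments are undirected: (i, j) and (j, i) denote the same record, and
    :attr:`key` gives the canonical order-independent identifier.
    """

    segment_id: tuple[str, str]
    length_km: float
    road_type: str
    vehicle_density: TimeProfile   # M_ij(t), veh/km
    population_density: TimeProfile  # T_ij(t), persons/m^2
    wind_speed: TimeProfile        # v^Wind_ij(t), m/s, strictly positive
    region: str = "city"
    land_use: str = "mixed"
    water: WaterAttributes = field(default_factory=WaterAttributes)

    def __post_init__(self) -> None:
        sid = (str(self.segment_id[0]), str(self.segment_id[1]))
        object.__setattr__(self, "segment_id", sid)
        _require(self.length_km > 0,
                 f"segment {self.label}: length must be > 0, got {self.length_km}")
        _require(self.road_type in ROAD_TYPES,
                 f"segment {self.label}: unknown road_type {self.road_type!r} "
                 f"(valid: {', '.join(ROAD_TYPES)})")
        _require(self.land_use in LAND_USES,
                 f"segment {self.label}: unknown land_use {self.land_use!r}")
        for t, v in enumerate(self.wind_speed):
            _require(v > 0,
                     f"segment {self.label}: wind_speed must be strictly positive "
                     f"(period {t} has {v}); wind speed divides the plume equation")

    @property
    def label(self) -> str:
        return f"({self.segment_id[0]}, {self.segment_id[1]})"

    @property
    def key(self) -> tuple[str, str]:
        """Canonical undirected identifier."""
        i, j = self.segment_id
        return (i, j) if i <= j else (j, i)


@dataclass(frozen=True)
class RoadNetwork:
    """A road network G = (U, V): node ids and road segments.

    ``node_coords`` is optional planar decoration (e.g. for GeoJSON export);
    it is never used numerically.
    """

    nodes: frozenset[str]
    segments: tuple[RoadSegment, ...]
    node_coords: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(str(n) for n in self.nodes))
        object.__setattr__(self, "segments", tuple(self.segments))
        seen: set[tuple[str, str]] = set()
        for seg in self.segments:
            for endpoint in seg.segment_id:
                _require(endpoint in self.nodes,
                         f"segment {seg.label}: endpoint {endpoint!r} not in node set")
            _require(seg.key not in seen,
                     f"duplicate segment {seg.label} (segments are undirected)")
            seen.add(seg.key)

    def __len__(self) -> int:
        return len(self.segments)

    def get_segment(self, i: str, j: str) -> RoadSegment:
        want = (str(i), str(j)) if str(i) <= str(j) else (str(j), str(i))
        for seg in self.segments:
            if seg.key == want:
                return seg
        raise KeyError(f"no segment ({i}, {j}) in network")


@dataclass(frozen=True)
class ReleaseScenario:
    """A chemical release description.

    total_amount_mg
        Q, the total amount released into each water medium, mg.
    release_rate_mg_s
        Q^Hazard, the release rate feeding the atmospheric plume, mg/s.
    aegl_thresholds
        (C_1^Pop, C_2^Pop, C_3^Pop) in mg/m^3, strictly increasing: AEGL-1
        is the lowest (discomfort) and AEGL-3 the highest (life-threatening)
        concentration, so the AEGL-1 ring is the outermost.
    env_thresholds
        (C_1..C_4)^Env in mg/m^3 for air, groundwater, lake, river. The air
        limit equals the AEGL-2 value by definition.
    elapsed_times_s
        (t^Gwater, t^Lake, t^River): time since release into each water
        medium, s — the assessment horizon, distinct from the time-of-day
        index which only selects profile values.
    friction_velocity
        u* of the water flow, m/s, within [0.02, 0.553].
    """

    chemical_name: str
    total_amount_mg: float
    release_rate_mg_s: float
    aegl_thresholds: tuple[float, float, float]
    env_thresholds: tuple[float, float, float, float]
    elapsed_times_s: tuple[float, float, float]
    friction_velocity: float
    source_height_m: float = 0.0

    def __post_init__(self) -> None:
        _require(self.total_amount_mg > 0, "total amount Q must be > 0")
        _require(self.release_rate_mg_s > 0, "release rate Q^Hazard must be > 0")
        _require(self.source_height_m >= 0, "source height must be >= 0")
        c1, c2, c3 = self.aegl_thresholds
        _require(0 < c1 < c2 < c3,
                 "AEGL thresholds must satisfy 0 < AEGL-1 < AEGL-2 < AEGL-3, "
                 f"got {self.aegl_thresholds}")
        _require(len(self.env_thresholds) == 4, "need 4 environmental thresholds")
        for c in self.env_thresholds:
            _require(c > 0, "environmental thresholds must be > 0")
        _require(math.isclose(self.env_thresholds[0], c2, rel_tol=1e-12),
                 "the air pollution limit C_1^Env must equal the AEGL-2 threshold")
        for te in self.elapsed_times_s:
            _require(te > 0, "elapsed diffusion times must be > 0")
        lo, hi = FRICTION_VELOCITY_BOUNDS
        _require(lo <= self.friction_velocity <= hi,
                 f"friction velocity u* must lie in [{lo}, {hi}], "
                 f"got {self.friction_velocity}")


@dataclass(frozen=True)
class StabilityParameters:
    """Power-law dispersion coefficients: sigma_y = a*x^c, sigma_z = b*x^d
    with x in metres."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        _require(self.a > 0 and self.b > 0, "a and b must be > 0")
        _require(self.c > 0 and self.d > 0, "c and d must be > 0")

    def sigma_y(self, x: float) -> float:
        return self.a * x ** self.c

    def sigma_z(self, x: float) -> float:
        return self.b * x ** self.d


def normalize_population_density(value_per_km2: float) -> float:
    """Convert persons/km^2 to the internal persons/m^2 convention."""
    if value_per_km2 < 0:
        raise NetworkValidationError(
            f"population density must be >= 0, got {value_per_km2}")
    return value_per_km2 * 1e-6


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PROFILE_QUANTITIES = {
    "vehicle_density": ("vehicle_density", None),
    "population_density": ("population_density", None),
    "wind_speed": ("wind_speed", None),
    "groundwater_flow": ("water", "groundwater"),
    "river_flow": ("water", "river"),
}


def _segment_to_dict(seg: RoadSegment) -> dict:
    d: dict = {
        "segment_id": list(seg.segment_id),
        "length_km": seg.length_km,
        "road_type": seg.road_type,
        "region": seg.region,
        "land_use": seg.land_use,
        "vehicle_density": list(seg.vehicle_density),
        "population_density": list(seg.population_density),
        "wind_speed": list(seg.wind_speed),
    }
    w = seg.water
    water: dict = {}
    if w.groundwater is not None:
        water["groundwater"] = {
            "flow_profile": list(w.groundwater.flow_profile),
            "depth": w.groundwater.depth,
            "wet_cross_section": w.groundwater.wet_cross_section,
        }
    if w.lake is not None:
        water["lake"] = {"depth": w.lake.depth, "relation": w.lake.relation}
    if w.river is not None:
        water["river"] = {
            "flow_profile": list(w.river.flow_profile),
            "depth": w.river.depth,
            "width": w.river.width,
            "relation": w.river.relation,
        }
    if water:
        d["water"] = water
    return d


def _segment_from_dict(d: Mapping) -> RoadSegment:
    def profile(key: str, source: Mapping) -> TimeProfile:
        try:
            raw = source[key]
        except KeyError as exc:
            raise NetworkValidationError(
                f"segment {d.get('segment_id')}: missing field {key!r}") from exc
        return TimeProfile(tuple(raw))

    water_d = d.get("water", {}) or {}
    gw = water_d.get("groundwater")
    lake = water_d.get("lake")
    river = water_d.get("river")
    water = WaterAttributes(
        groundwater=GroundwaterAttributes(
            flow_profile=profile("flow_profile", gw),
            depth=float(gw["depth"]),
            wet_cross_section=float(gw["wet_cross_section"]),
        ) if gw else None,
        lake=LakeAttributes(
            depth=float(lake["depth"]), relation=lake["relation"],
        ) if lake else None,
        river=RiverAttributes(
            flow_profile=profile("flow_profile", river),
            depth=float(river["depth"]),
            width=float(river["width"]),
            relation=river["relation"],
        ) if river else None,
    )
    missing = [k for k in ("segment_id", "length_km", "road_type") if k not in d]
    if missing:
        raise NetworkValidationError(
            f"segment {d.get('segment_id')}: missing field(s) {missing}")
    return RoadSegment(
        segment_id=tuple(d["segment_id"]),
        length_km=float(d["length_km"]),
        road_type=d["road_type"],
        region=d.get("region", "city"),
        land_use=d.get("land_use", "mixed"),
        vehicle_density=profile("vehicle_density", d),
        population_density=profile("population_density", d),
        wind_speed=profile("wind_speed", d),
        water=water,
    )


def network_to_dict(net: RoadNetwork) -> dict:
    d: dict = {
        "nodes": sorted(net.nodes),
        "segments": [_segment_to_dict(s) for s in net.segments],
    }
    if net.node_coords is not None:
        d["node_coords"] = {k: list(v) for k, v in sorted(net.node_coords.items())}
    return d


def network_from_dict(d: Mapping) -> RoadNetwork:
    coords = d.get("node_coords")
    return RoadNetwork(
        nodes=frozenset(d["nodes"]),
        segments=tuple(_segment_from_dict(s) for s in d["segments"]),
        node_coords={k: (float(v[0]), float(v[1])) for k, v in coords.items()}
        if coords else None,
    )


def _network_to_geojson(net: RoadNetwork) -> dict:
    features = []
    coords = net.node_coords or {}
    for seg in net.segments:
        i, j = seg.segment_id
        geometry = None
        if i in coords and j in coords:
            geometry = {"type": "LineString",
                        "coordinates": [list(coords[i]), list(coords[j])]}
        features.append({
            "type": "Feature",
            "geometry": geometry,
            "properties": _segment_to_dict(seg),
        })
    return {
        "type": "FeatureCollection",
        "features": features,
        "nodes": sorted(net.nodes),
        "node_coords": {k: list(v) for k, v in sorted(coords.items())} or None,
    }


def _network_from_geojson(d: Mapping) -> RoadNetwork:
    segments = tuple(_segment_from_dict(f["properties"]) for f in d["features"])
    nodes = d.get("nodes")
    if nodes is None:
        nodes = {n for s in segments for n in s.segment_id}
    coords = d.get("node_coords")
    return RoadNetwork(
        nodes=frozenset(nodes),
        segments=segments,
        node_coords={k: (float(v[0]), float(v[1])) for k, v in coords.items()}
        if coords else None,
    )


# CSV bundle: segments.csv (scalars), profiles.csv (long), water.csv (long)

def _network_to_csv_bundle(net: RoadNetwork, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "segments.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_i", "node_j", "length_km", "road_type", "region", "land_use"])
        for seg in net.segments:
            w.writerow([*seg.segment_id, repr(seg.length_km), seg.road_type,
                        seg.region, seg.land_use])
    with open(os.path.join(directory, "profiles.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_i", "node_j", "quantity", "period", "value"])
        for seg in net.segments:
            rows = {
                "vehicle_density": seg.vehicle_density,
                "population_density": seg.population_density,
                "wind_speed": seg.wind_speed,
            }
            if seg.water.groundwater is not None:
                rows["groundwater_flow"] = seg.water.groundwater.flow_profile
            if seg.water.river is not None:
                rows["river_flow"] = seg.water.river.flow_profile
            for qty, prof in rows.items():
                for t, v in enumerate(prof):
                    w.writerow([*seg.segment_id, qty, t, repr(v)])
    with open(os.path.join(directory, "water.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_i", "node_j", "medium", "param", "value"])
        for seg in net.segments:
            wa = seg.water
            if wa.groundwater is not None:
                w.writerow([*seg.segment_id, "groundwater", "depth",
                            repr(wa.groundwater.depth)])
                w.writerow([*seg.segment_id, "groundwater", "wet_cross_section",
                            repr(wa.groundwater.wet_cross_section)])
            if wa.lake is not None:
                w.writerow([*seg.segment_id, "lake", "depth", repr(wa.lake.depth)])
                w.writerow([*seg.segment_id, "lake", "relation", wa.lake.relation])
            if wa.river is not None:
                w.writerow([*seg.segment_id, "river", "depth", repr(wa.river.depth)])
                w.writerow([*seg.segment_id, "river", "width", repr(wa.river.width)])
                w.writerow([*seg.segment_id, "river", "relation", wa.river.relation])


def _network_from_csv_bundle(directory: str) -> RoadNetwork:
    def read(name: str) -> list[dict]:
        with open(os.path.join(directory, name), newline="") as fh:
            return list(csv.DictReader(fh))

    seg_rows = read("segments.csv")
    prof_rows = read("profiles.csv")
    water_rows = read("water.csv") if os.path.exists(
        os.path.join(directory, "water.csv")) else []

    profiles: dict[tuple[str, str, str], dict[int, float]] = {}
    for r in prof_rows:
        key = (r["node_i"], r["node_j"], r["quantity"])
        profiles.setdefault(key, {})[int(r["period"])] = float(r["value"])

    water: dict[tuple[str, str], dict[str, dict[str, object]]] = {}
    for r in water_rows:
        key = (r["node_i"], r["node_j"])
        med = water.setdefault(key, {}).setdefault(r["medium"], {})
        med[r["param"]] = r["value"]

    def get_profile(i: str, j: str, qty: str) -> TimeProfile:
        per = profiles.get((i, j, qty))
        if per is None:
            raise NetworkValidationError(
                f"segment ({i}, {j}): missing profile {qty!r} in profiles.csv")
        if sorted(per) != list(range(N_PERIODS)):
            raise NetworkValidationError(
                f"segment ({i}, {j}): profile {qty!r} does not cover periods 0..23")
        return TimeProfile(tuple(per[t] for t in range(N_PERIODS)))

    segments = []
    for r in seg_rows:
        i, j = r["node_i"], r["node_j"]
        wmed = water.get((i, j), {})
        gw = wmed.get("groundwater")
        lake = wmed.get("lake")
        river = wmed.get("river")
        segments.append(RoadSegment(
            segment_id=(i, j),
            length_km=float(r["length_km"]),
            road_type=r["road_type"],
            region=r.get("region", "city"),
            land_use=r.get("land_use", "mixed"),
            vehicle_density=get_profile(i, j, "vehicle_density"),
            population_density=get_profile(i, j, "population_density"),
            wind_speed=get_profile(i, j, "wind_speed"),
            water=WaterAttributes(
                groundwater=GroundwaterAttributes(
                    flow_profile=get_profile(i, j, "groundwater_flow"),
                    depth=float(gw["depth"]),
                    wet_cross_section=float(gw["wet_cross_section"]),
                ) if gw else None,
                lake=LakeAttributes(
                    depth=float(lake["depth"]), relation=str(lake["relation"]),
                ) if lake else None,
                river=RiverAttributes(
                    flow_profile=get_profile(i, j, "river_flow"),
                    depth=float(river["depth"]),
                    width=float(river["width"]),
                    relation=str(river["relation"]),
                ) if river else None,
            ),
        ))
    nodes = {n for s in segments for n in s.segment_id}
    return RoadNetwork(nodes=frozenset(nodes), segments=tuple(segments))


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if os.path.isdir(path):
        return "csv-bundle"
    if path.endswith(".geojson"):
        return "geojson"
    return "json"


def save_network(net: RoadNetwork, path: str, format: str | None = None) -> None:
    """Write a network as JSON, GeoJSON FeatureCollection, or a CSV bundle
    directory (segments.csv / profiles.csv / water.csv)."""
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(network_to_dict(net), fh, indent=1)
    elif fmt == "geojson":
        with open(path, "w") as fh:
            json.dump(_network_to_geojson(net), fh, indent=1)
    elif fmt == "csv-bundle":
        _network_to_csv_bundle(net, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (json, geojson, csv-bundle)")


def load_network(path: str, format: str | None = None) -> RoadNetwork:
    """Load and validate a network; raises :class:`NetworkValidationError`
    naming the offending segment and field on any invariant violation."""
    fmt = _infer_format(path, format)
    if fmt == "csv-bundle":
        return _network_from_csv_bundle(path)
    with open(path) as fh:
        d = json.load(fh)
    if fmt == "geojson" or d.get("type") == "FeatureCollection":
        return _network_from_geojson(d)
    return network_from_dict(d)


def scenario_to_dict(sc: ReleaseScenario) -> dict:
    return {
        "chemical_name": sc.chemical_name,
        "total_amount_mg": sc.total_amount_mg,
        "release_rate_mg_s": sc.release_rate_mg_s,
        "source_height_m": sc.source_height_m,
        "aegl_thresholds": list(sc.aegl_thresholds),
        "env_thresholds": list(sc.env_thresholds),
        "elapsed_times_s": list(sc.elapsed_times_s),
        "friction_velocity": sc.friction_velocity,
    }


def scenario_from_dict(d: Mapping) -> ReleaseScenario:
    return ReleaseScenario(
        chemical_name=d["chemical_name"],
        total_amount_mg=float(d["total_amount_mg"]),
        release_rate_mg_s=float(d["release_rate_mg_s"]),
        source_height_m=float(d.get("source_height_m", 0.0)),
        aegl_thresholds=tuple(float(x) for x in d["aegl_thresholds"]),
        env_thresholds=tuple(float(x) for x in d["env_thresholds"]),
        elapsed_times_s=tuple(float(x) for x in d["elapsed_times_s"]),
        friction_velocity=float(d["friction_velocity"]),
    )


def save_scenario(sc: ReleaseScenario, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(scenario_to_dict(sc), fh, indent=1)


def load_scenario(path: str) -> ReleaseScenario:
    with open(path) as fh:
        return scenario_from_dict(json.load(fh))
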