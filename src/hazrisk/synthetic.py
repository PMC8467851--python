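"""Seeded generator of metropolitan-style road networks and diurnal profiles.

Emulates a simplified suburban-district network (default 38 nodes, 52 arcs)
so every stage of the risk chain can be exercised without external data:

* vehicle densities peak during the morning (07-09) and afternoon (17-19)
  rush hours;
* population-density profiles follow land-use archetypes — residential
  (higher at night), commercial (higher in the daytime), boarding school
  (similar day and night), mixed;
* wind speed follows a diurnal cycle (afternoon maximum), strictly positive;
* a subset of segments carries groundwater, lake and river attributes, with
  both 'alongside' and 'crossing' road/water relations represented, and
  characteristic speed scales wind >> river >> groundwater (defaults about
  3, 0.3 and 0.003 m/s with a +/-50% diurnal swing).

All randomness flows through one seeded numpy generator; a fixed seed gives
byte-identical output. The default release scenario is a 6-ton gaseous
ammonia load released over 600 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import (
    N_PERIODS,
    GroundwaterAttributes,
    LakeAttributes,
    ReleaseScenario,
    RiverAttributes,
    RoadNetwork,
    RoadSegment,
    TimeProfile,
    WaterAttributes,
)

__all__ = [
    "AMMONIA_THRESHOLDS",
    "GeneratorConfig",
    "generate_network",
    "generate_scenario",
    "default_scenario",
    "RUSH_PERIODS",
]

#: Periods counted as rush hours.
RUSH_PERIODS = (7, 8, 9, 17, 18, 19)

#: Illustrative concentration limits for gaseous ammonia, mg/m^3: the three
#: public 60-min AEGL values (30 / 160 / 1100 ppm converted at 25 C), and
#: water limits in the spirit of ambient ammonia-nitrogen quality standards.
#: These are plausible defaults for synthetic studies, not regulatory data.
AMMONIA_THRESHOLDS: dict[str, tuple[float, ...]] = {
    "aegl": (21.0, 111.0, 766.0),
    "water": (500.0, 1000.0, 1000.0),  # groundwater, lake, river (mg/m^3)
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-network generator; defaults give the standard
    38-node / 52-arc study network."""

    n_nodes: int = 38
    n_segments: int = 52
    seed: int = 0
    # land-use mixture over segments
    land_use_mix: Mapping[str, float] = field(default_factory=lambda: {
        "residential": 0.40, "commercial": 0.30, "school": 0.10, "mixed": 0.20})
    # traffic: off-peak base and rush-hour peak vehicle densities (veh/km)
    vehicle_base: float = 15.0
    vehicle_peak: float = 55.0
    # population density scale, persons/m^2 (0.01 = 10,000 persons/km^2)
    population_scale: float = 0.01
    # wind: diurnal mean and fractional amplitude (m/s, afternoon maximum)
    wind_mean: float = 3.0
    wind_amplitude: float = 0.5
    # water bodies: assignment probabilities and flow scales (m/s)
    p_groundwater: float = 0.35
    p_lake: float = 0.20
    p_river: float = 0.25
    river_speed_mean: float = 0.3
    groundwater_speed_mean: float = 0.003
    water_amplitude: float = 0.5
    # release scenario defaults
    total_tons: float = 6.0
    release_duration_s: float = 600.0
    elapsed_time_s: float = 3600.0
    friction_velocity: float = 0.1
    thresholds: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(AMMONIA_THRESHOLDS))

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_segments < self.n_nodes - 1:
            raise ValueError(
                f"{self.n_segments} segments cannot connect {self.n_nodes} nodes "
                f"(need at least {self.n_nodes - 1})")
        if self.n_segments > self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("more segments than node pairs")


def _diurnal(phase_peak: float, amplitude: float) -> np.ndarray:
    """Unit-mean sinusoid over 24 periods peaking at ``phase_peak`` hours."""
    t = np.arange(N_PERIODS)
    return 1.0 + amplitude * np.cos(2.0 * np.pi * (t - phase_peak) / N_PERIODS)


def _vehicle_profile(rng: np.random.Generator, cfg: GeneratorConfig) -> TimeProfile:
    t = np.arange(N_PERIODS)
    bump = (np.exp(-((t - 8.0) / 1.5) ** 2) + np.exp(-((t - 18.0) / 1.5) ** 2))
    base = cfg.vehicle_base * (0.4 + 0.6 * _diurnal(13.0, 0.4))
    prof = base + (cfg.vehicle_peak - cfg.vehicle_base) * bump
    # mild multiplicative jitter; small enough to keep the maximum in a
    # rush-hour period (the bump dominates by construction)
    prof = prof * rng.uniform(0.95, 1.05, size=N_PERIODS)
    return TimeProfile(tuple(prof))


def _population_profile(
    rng: np.random.Generator, cfg: GeneratorConfig, land_use: str,
) -> TimeProfile:
    t = np.arange(N_PERIODS)
    day = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - 13.0) / N_PERIODS))  # 1 midday
    if land_use == "residential":
        shape = 1.3 - 0.6 * day          # higher at night
    elif land_use == "commercial":
        shape = 0.5 + 1.0 * day          # higher in the daytime
    elif land_use == "school":
        shape = np.full(N_PERIODS, 1.0)  # boarding school: similar day/night
    else:
        shape = 0.9 + 0.2 * day
    scale = cfg.population_scale * rng.uniform(0.5, 1.5)
    prof = scale * shape * rng.uniform(0.97, 1.03, size=N_PERIODS)
    return TimeProfile(tuple(prof))


def _wind_profile(rng: np.random.Generator, cfg: GeneratorConfig) -> TimeProfile:
    prof = cfg.wind_mean * _diurnal(15.0, cfg.wind_amplitude)
    prof = prof * rng.uniform(0.95, 1.05, size=N_PERIODS)
    prof = np.maximum(prof, 0.2)  # strictly positive guard
    return TimeProfile(tuple(prof))


def _flow_profile(
    rng: np.random.Generator, mean: float, amplitude: float,
) -> TimeProfile:
    prof = mean * _diurnal(14.0, amplitude)
    prof = np.maximum(prof * rng.uniform(0.97, 1.03, size=N_PERIODS), 0.0)
    return TimeProfile(tuple(prof))


def _topology(
    rng: np.random.Generator, cfg: GeneratorConfig,
) -> tuple[dict[str, tuple[float, float]], list[tuple[str, str]]]:
    """Jittered-grid node placement plus a nearest-neighbour spanning tree
    and extra short chords — a planar-ish district road layout."""
    n = cfg.n_nodes
    side = math.ceil(math.sqrt(n))
    coords: dict[str, tuple[float, float]] = {}
    cells = [(r, c) for r in range(side) for c in range(side)][:n]
    spacing = 1.5  # km
    for k, (r, c) in enumerate(cells):
        jitter = rng.uniform(-0.35, 0.35, size=2) * spacing
        coords[str(k + 1)] = (c * spacing + jitter[0], r * spacing + jitter[1])

    names = list(coords)

    def dist(u: str, v: str) -> float:
        (x1, y1), (x2, y2) = coords[u], coords[v]
        return math.hypot(x1 - x2, y1 - y2)

    order = list(rng.permutation(names))
    placed = [order[0]]
    edges: list[tuple[str, str]] = []
    for node in order[1:]:
        nearest = min(placed, key=lambda p: dist(node, p))
        edges.append((node, nearest) if node < nearest else (nearest, node))
        placed.append(node)

    have = set(edges)
    candidates = sorted(
        ((dist(u, v), u, v)
         for a, u in enumerate(names) for v in names[a + 1:]
         if (u, v) not in have and (v, u) not in have),
        key=lambda x: x[0])
    for _, u, v in candidates:
        if len(edges) >= cfg.n_segments:
            break
        edges.append((u, v))
    return coords, edges


def generate_network(config: GeneratorConfig | None = None) -> RoadNetwork:
    """Generate a connected, fully validated synthetic road network."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    coords, edges = _topology(rng, cfg)

    land_uses = list(cfg.land_use_mix)
    probs = np.array([cfg.land_use_mix[k] for k in land_uses], dtype=float)
    probs = probs / probs.sum()

    road_types = ["two-lane", "undivided multilane", "divided multilane",
                  "cycle lane", "expressway"]
    type_probs = np.array([0.30, 0.25, 0.25, 0.10, 0.10])

    segments: list[RoadSegment] = []
    for idx, (i, j) in enumerate(edges):
        (x1, y1), (x2, y2) = coords[i], coords[j]
        length = max(0.3, math.hypot(x1 - x2, y1 - y2))
        land_use = str(rng.choice(land_uses, p=probs))
        road_type = str(rng.choice(road_types, p=type_probs))

        gw = None
        if rng.random() < cfg.p_groundwater:
            gw = GroundwaterAttributes(
                flow_profile=_flow_profile(
                    rng, cfg.groundwater_speed_mean, cfg.water_amplitude),
                depth=float(rng.uniform(3.0, 10.0)),
                wet_cross_section=float(rng.uniform(5.0, 20.0)),
            )
        lake = None
        if rng.random() < cfg.p_lake:
            lake = LakeAttributes(
                depth=float(rng.uniform(1.5, 4.0)),
                relation="alongside" if rng.random() < 0.5 else "crossing",
            )
        river = None
        if rng.random() < cfg.p_river:
            river = RiverAttributes(
                flow_profile=_flow_profile(
                    rng, cfg.river_speed_mean, cfg.water_amplitude),
                depth=float(rng.uniform(1.5, 5.0)),
                width=float(rng.uniform(20.0, 80.0)),
                relation="alongside" if rng.random() < 0.5 else "crossing",
            )

        segments.append(RoadSegment(
            segment_id=(i, j),
            length_km=length,
            road_type=road_type,
            region="city",
            land_use=land_use,
            vehicle_density=_vehicle_profile(rng, cfg),
            population_density=_population_profile(rng, cfg, land_use),
            wind_speed=_wind_profile(rng, cfg),
            water=WaterAttributes(groundwater=gw, lake=lake, river=river),
        ))

    segments = _ensure_water_coverage(segments, rng, cfg)
    return RoadNetwork(
        nodes=frozenset(coords),
        segments=tuple(segments),
        node_coords=coords,
    )


def _ensure_water_coverage(
    segments: list[RoadSegment], rng: np.random.Generator, cfg: GeneratorConfig,
) -> list[RoadSegment]:
    """Guarantee each water medium occurs and both road/water relations are
    represented among surface-water segments."""
    from dataclasses import replace

    def with_water(seg: RoadSegment, **kw) -> RoadSegment:
        return replace(seg, water=replace(seg.water, **kw))

    if len(segments) >= 4:
        if not any(s.water.groundwater for s in segments):
            segments[0] = with_water(segments[0], groundwater=GroundwaterAttributes(
                flow_profile=_flow_profile(
                    rng, cfg.groundwater_speed_mean, cfg.water_amplitude),
                depth=5.0, wet_cross_section=10.0))
        lake_rel = {s.water.lake.relation for s in segments if s.water.lake}
        for want, k in (("alongside", 1), ("crossing", 2)):
            if want not in lake_rel:
                segments[k] = with_water(segments[k], lake=LakeAttributes(
                    depth=2.5, relation=want))
        river_rel = {s.water.river.relation for s in segments if s.water.river}
        for want, k in (("alongside", 3), ("crossing", 0)):
            if want not in river_rel:
                segments[k] = with_water(segments[k], river=RiverAttributes(
                    flow_profile=_flow_profile(
                        rng, cfg.river_speed_mean, cfg.water_amplitude),
                    depth=3.0, width=40.0, relation=want))
    return segments


def generate_scenario(
    chemical: str = "ammonia",
    total_tons: float = 6.0,
    *,
    release_duration_s: float = 600.0,
    thresholds: Mapping[str, tuple[float, ...]] | None = None,
    elapsed_time_s: float = 3600.0,
    friction_velocity: float = 0.1,
) -> ReleaseScenario:
    """Build a release scenario from a load in metric tons.

    Q = tons x 1e9 mg; the plume feed rate Q^Hazard assumes the full load
    releases over ``release_duration_s`` (default 600 s). ``thresholds``
    must supply 'aegl' (3 increasing mg/m^3 values) and 'water'
    (groundwater, lake, river limits, mg/m^3); the air limit is tied to
    AEGL-2.
    """
    if total_tons <= 0:
        raise ValueError(f"load must be > 0 tons, got {total_tons}")
    if release_duration_s <= 0:
        raise ValueError("release duration must be > 0 s")
    if thresholds is None:
        raise ValueError(
            "concentration thresholds are required: pass a mapping with "
            "'aegl' (3 values) and 'water' (groundwater, lake, river limits)")
    aegl = tuple(float(c) for c in thresholds["aegl"])
    water = tuple(float(c) for c in thresholds["water"])
    if len(aegl) != 3 or len(water) != 3:
        raise ValueError("need 3 AEGL and 3 water thresholds")
    q_total = total_tons * 1e9  # mg
    return ReleaseScenario(
        chemical_name=chemical,
        total_amount_mg=q_total,
        release_rate_mg_s=q_total / release_duration_s,
        aegl_thresholds=aegl,
        env_thresholds=(aegl[1], *water),
        elapsed_times_s=(elapsed_time_s,) * 3,
        friction_velocity=friction_velocity,
    )


def default_scenario(config: GeneratorConfig | None = None) -> ReleaseScenario:
    """The generator's study scenario (6 t ammonia by default)."""
    cfg = config or GeneratorConfig()
    return generate_scenario(
        "ammonia",
        cfg.total_tons,
        release_duration_s=cfg.release_duration_s,
        thresholds=cfg.thresholds,
        elapsed_time_s=cfg.elapsed_time_s,
        friction_velocity=cfg.friction_velocity,
    )
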