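"""Bearing-capacity ratios, risk-preference transforms and risk scores.

A raw segment-period risk would be probability x consequence. To keep
low-probability / catastrophic-consequence cases visible, the consequence
is first raised to a preference exponent q chosen from how the consequence
compares with the bearing capacity of the assessed area:

* population: p_pop = exposed population / acceptable limit, where the
  limit is the population within a corridor of width d_pop (600 m, the
  emergency-response isolation guideline) along the segment;
* environment: p_env = released amount Q / sum_r V_r * C_r, the combined
  self-purification capacity of the polluted media.

q steps through {0.9, 0.95, 1.0, 1.05, 1.1} as p crosses 0.5, 1 and 1.5 —
damping within-capacity consequences and amplifying over-capacity ones —
and the final scores are

    ER_pop(t) = P(t) * C_pop(t)^q_pop      ER_env(t) = P(t) * C_env(t)^q_env

Because C^q is unit-sensitive, scores are comparable only within one
currency unit system, and ER_pop / ER_env are reported separately, never
summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .accident import segment_leakage_probability, lookup_leakage_conditional, \
    DEFAULT_ACCIDENT_SCENARIO
from .consequences import (
    CostIncidence,
    DEFAULT_ENV_COSTS,
    DEFAULT_INCIDENCE,
    DEFAULT_POP_COSTS,
    EnvCostTable,
    PopulationCostTable,
    environmental_consequence,
    population_consequence,
)
from .network import N_PERIODS, ReleaseScenario, RoadNetwork, RoadSegment, \
    StabilityParameters
from .plume import ExposureZones, exposure_zones
from .water import PollutionVolumes, pollution_volumes

__all__ = [
    "DEFAULT_BEARING_WIDTH_M",
    "PREFERENCE_LEVELS",
    "AssessmentConfig",
    "RiskRecord",
    "population_ratio",
    "environment_ratio",
    "preference_parameter",
    "population_risk",
    "environmental_risk",
    "assess_segment",
    "assess_network",
    "route_risk",
    "rank_segments",
]

#: Width of the population bearing corridor, m (emergency-response
#: isolation-distance guideline).
DEFAULT_BEARING_WIDTH_M = 600.0

#: The admissible preference exponents, in bracket order.
PREFERENCE_LEVELS = (0.9, 0.95, 1.0, 1.05, 1.1)


@dataclass(frozen=True)
class AssessmentConfig:
    """Everything the assessment needs beyond network + scenario + stability."""

    pop_costs: PopulationCostTable = DEFAULT_POP_COSTS
    env_costs: EnvCostTable = DEFAULT_ENV_COSTS
    incidence: CostIncidence = DEFAULT_INCIDENCE
    bearing_width_m: float = DEFAULT_BEARING_WIDTH_M
    accident_scenario: str = DEFAULT_ACCIDENT_SCENARIO
    rate_table: Mapping[tuple[str, str], float] | None = None
    leakage_table: Mapping[str, float] | None = None
    use_length_squared: bool = False

    def leakage_conditional(self) -> float:
        return lookup_leakage_conditional(self.accident_scenario, self.leakage_table)


@dataclass(frozen=True)
class RiskRecord:
    """One fully assessed segment-period."""

    segment_id: tuple[str, str]
    period: int
    probability: float
    c_pop: float
    c_env: float
    p_pop: float
    q_pop: float
    p_env: float
    q_env: float
    er_pop: float
    er_env: float
    zones: ExposureZones
    volumes: PollutionVolumes


def population_ratio(
    zones: ExposureZones,
    population_density: float,
    length_km: float,
    bearing_width_m: float = DEFAULT_BEARING_WIDTH_M,
) -> float:
    """Ratio of the exposed population to the bearing corridor's population.

    p = (sum_u S_u * T) / (10^3 * L * d_pop * T); the density cancels
    algebraically but must be > 0 for the ratio to be defined.
    """
    if length_km <= 0:
        raise ValueError("segment length must be > 0")
    if bearing_width_m <= 0:
        raise ValueError("bearing width must be > 0")
    if population_density <= 0:
        raise ValueError(
            "population ratio undefined for zero population density")
    total_area = sum(zones.areas)
    return total_area / (1e3 * length_km * bearing_width_m)


def environment_ratio(
    total_amount_mg: float,
    volumes: PollutionVolumes,
    env_thresholds: Sequence[float],
) -> float:
    """Ratio of the released amount to the environmental bearing capacity
    sum_r V_r * C_r (the amount the polluted volumes can hold at their limit
    concentrations)."""
    capacity = sum(v * c for v, c in zip(volumes.volumes, env_thresholds))
    if capacity <= 0:
        raise ValueError(
            "environmental bearing capacity is zero (no polluted volume); "
            "the ratio is undefined")
    return total_amount_mg / capacity


def preference_parameter(p: float) -> float:
    """Piecewise risk-preference exponent q(p).

    0 < p <= 0.5 -> 0.9;  0.5 < p < 1 -> 0.95;  p = 1 -> 1.0;
    1 < p <= 1.5 -> 1.05;  p > 1.5 -> 1.1.  p = 0 maps to 0.9 (the
    consequence is zero there, so the choice never affects the score).
    """
    if p < 0:
        raise ValueError(f"bearing ratio must be >= 0, got {p}")
    if p <= 0.5:
        return 0.9
    if p < 1.0:
        return 0.95
    if p == 1.0:
        return 1.0
    if p <= 1.5:
        return 1.05
    return 1.1


def _powered_risk(probability: float, consequence: float, q: float) -> float:
    if probability < 0 or consequence < 0:
        raise ValueError("probability and consequence must be >= 0")
    if consequence == 0.0:
        return 0.0
    # log-domain evaluation avoids overflow for large consequences with q > 1
    return probability * math.exp(q * math.log(consequence))


def population_risk(probability: float, c_pop: float, q_pop: float) -> float:
    """ER_pop = P * C_pop^q_pop; recovers the traditional P*C at q = 1."""
    return _powered_risk(probability, c_pop, q_pop)


def environmental_risk(probability: float, c_env: float, q_env: float) -> float:
    """ER_env = P * C_env^q_env."""
    return _powered_risk(probability, c_env, q_env)


def assess_segment(
    segment: RoadSegment,
    scenario: ReleaseScenario,
    stability: StabilityParameters,
    config: AssessmentConfig | None = None,
    t: int = 0,
) -> RiskRecord:
    """Full risk chain for one segment-period; deterministic given inputs.

    A zero population density short-circuits the (undefined) population
    ratio to p = 0, q = 0.9 — the population consequence is zero there, so
    the score is unaffected.
    """
    cfg = config or AssessmentConfig()
    prob = segment_leakage_probability(
        segment, t, cfg.leakage_conditional(),
        rate_table=cfg.rate_table,
        use_length_squared=cfg.use_length_squared)

    zones = exposure_zones(scenario, stability, segment.wind_speed[t])
    t_pop = segment.population_density[t]
    c_pop = population_consequence(zones, t_pop, cfg.incidence, cfg.pop_costs, t)
    if t_pop > 0:
        p_pop = population_ratio(zones, t_pop, segment.length_km,
                                 cfg.bearing_width_m)
    else:
        p_pop = 0.0
    q_pop = preference_parameter(p_pop)

    volumes = pollution_volumes(segment, scenario, stability, t)
    c_env = environmental_consequence(volumes, cfg.env_costs)
    p_env = environment_ratio(scenario.total_amount_mg, volumes,
                              scenario.env_thresholds)
    q_env = preference_parameter(p_env)

    return RiskRecord(
        segment_id=segment.segment_id,
        period=t,
        probability=prob,
        c_pop=c_pop,
        c_env=c_env,
        p_pop=p_pop,
        q_pop=q_pop,
        p_env=p_env,
        q_env=q_env,
        er_pop=population_risk(prob, c_pop, q_pop),
        er_env=environmental_risk(prob, c_env, q_env),
        zones=zones,
        volumes=volumes,
    )


def record_to_row(rec: RiskRecord) -> dict:
    i, j = rec.segment_id
    row = {
        "node_i": i,
        "node_j": j,
        "period": rec.period,
        "probability": rec.probability,
        "c_pop": rec.c_pop,
        "c_env": rec.c_env,
        "p_pop": rec.p_pop,
        "q_pop": rec.q_pop,
        "p_env": rec.p_env,
        "q_env": rec.q_env,
        "er_pop": rec.er_pop,
        "er_env": rec.er_env,
        "r_pop_1": rec.zones.radii[0],
        "r_pop_2": rec.zones.radii[1],
        "r_pop_3": rec.zones.radii[2],
    }
    for k, name in enumerate(("air", "gwater", "lake", "river")):
        row[f"r_{name}"] = rec.volumes.radii[k]
        row[f"v_{name}"] = rec.volumes.volumes[k]
    return row


def assess_network(
    network: RoadNetwork,
    scenario: ReleaseScenario,
    stability: StabilityParameters,
    config: AssessmentConfig | None = None,
) -> pd.DataFrame:
    """Assess every segment over all 24 periods.

    Returns a tidy DataFrame with one row per segment-period carrying every
    risk-record field; segments are independent (an accident on one segment
    does not affect others).
    """
    rows = []
    for seg in network.segments:
        for t in range(N_PERIODS):
            try:
                rows.append(record_to_row(
                    assess_segment(seg, scenario, stability, config, t)))
            except Exception as exc:
                raise RuntimeError(
                    f"assessment failed for segment {seg.label} "
                    f"period {t}: {exc}") from exc
    return pd.DataFrame(rows)


def route_risk(
    records: pd.DataFrame,
    route: Iterable[tuple[str, str]],
    t: int,
) -> tuple[float, float]:
    """Route-level risk at period t: component-wise sum of (ER_pop, ER_env)
    over the route's segments (the traditional additive route aggregation)."""
    er_pop = 0.0
    er_env = 0.0
    for i, j in route:
        i, j = str(i), str(j)
        mask = (records["period"] == t) & (
            ((records["node_i"] == i) & (records["node_j"] == j))
            | ((records["node_i"] == j) & (records["node_j"] == i)))
        sub = records[mask]
        if sub.empty:
            raise KeyError(f"segment ({i}, {j}) at period {t} not in records")
        er_pop += float(sub["er_pop"].iloc[0])
        er_env += float(sub["er_env"].iloc[0])
    return er_pop, er_env


def rank_segments(
    records: pd.DataFrame, by: str = "er_pop", stat: str = "max",
) -> pd.DataFrame:
    """Per-segment summary ranked by a risk column, highest first.

    Includes the argmax period and a flag for segments with any over-capacity
    (q > 1) period — the catastrophic-consequence candidates.
    """
    if by not in records.columns:
        raise KeyError(f"unknown column {by!r}")
    grouped = records.groupby(["node_i", "node_j"], sort=False)
    out = grouped.agg(
        max_value=(by, "max"),
        mean_value=(by, "mean"),
        argmax_period=(by, lambda s: int(records.loc[s.idxmax(), "period"])),
        any_q_pop_gt_1=("q_pop", lambda s: bool((s > 1).any())),
        any_q_env_gt_1=("q_env", lambda s: bool((s > 1).any())),
    ).reset_index()
    return out.sort_values("max_value", ascending=False, ignore_index=True)
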