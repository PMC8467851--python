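"""Leakage accident probability per segment and period.

The leakage probability chain is::

    P^C = P^A x P^B                      (rate, per million vehicle-km)
    P_ij(t) = 1e-6 x P^A x P^B x M_ij(t) x L_ij / 2   (dimensionless)

where P^A is a weighted-average truck accident rate looked up by
(region, road type), P^B the conditional probability that an accident of a
given type leads to a leak, M_ij(t) the vehicle density (veh/km) and L_ij
the segment length (km). The final L/2 reflects per-direction traffic on an
undirected segment; ``use_length_squared=True`` switches to an L^2 reading.
"""

from __future__ import annotations

import csv
import warnings
from typing import Iterable, Mapping

from .network import N_PERIODS, RoadSegment

__all__ = [
    "DEFAULT_ACCIDENT_RATES",
    "DEFAULT_LEAKAGE_CONDITIONALS",
    "DEFAULT_ACCIDENT_SCENARIO",
    "LookupError_",
    "lookup_truck_accident_rate",
    "lookup_leakage_conditional",
    "combined_leakage_conditional",
    "leakage_rate",
    "segment_leakage_probability",
    "load_rate_table",
    "load_leakage_table",
]

#: Weighted-average truck accident rates, accidents per million vehicle-km,
#: keyed by (region, road_type).
DEFAULT_ACCIDENT_RATES: dict[tuple[str, str], float] = {
    ("city", "two-lane"): 5.38,
    ("city", "undivided multilane"): 8.65,
    ("city", "divided multilane"): 7.75,
    ("city", "cycle lane"): 6.03,
    ("city", "expressway"): 1.35,
}

#: Conditional leakage probability given an accident of each type. The first
#: three are single-vehicle noncollision scenarios, the rest single-vehicle
#: collision scenarios.
DEFAULT_LEAKAGE_CONDITIONALS: dict[str, float] = {
    "leaves the road": 0.331,
    "overturned on the road": 0.375,
    "other noncollision accident": 0.169,
    "collision with stopped vehicle": 0.031,
    "collision with a train": 0.455,
    "collision with a nonmotorized vehicle": 0.015,
    "collision with fixed objects": 0.129,
    "other collision accident": 0.059,
}

#: Default accident scenario: the consequence model assumes hazmat leaks
#: immediately after the vehicle overturns on the road.
DEFAULT_ACCIDENT_SCENARIO = "overturned on the road"


class LookupError_(KeyError):
    """Unknown (region, road_type) or accident-scenario key."""


def lookup_truck_accident_rate(
    region: str,
    road_type: str,
    table: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Truck accident rate P^A (accidents per million vehicle-km)."""
    tbl = DEFAULT_ACCIDENT_RATES if table is None else table
    key = (region, road_type)
    if key not in tbl:
        valid = ", ".join(f"{k}" for k in sorted(tbl))
        raise LookupError_(
            f"no accident rate for {key}; valid (region, road_type) keys: {valid}")
    return tbl[key]


def lookup_leakage_conditional(
    scenario: str, table: Mapping[str, float] | None = None,
) -> float:
    """Conditional leakage probability P^B for one accident scenario."""
    tbl = DEFAULT_LEAKAGE_CONDITIONALS if table is None else table
    if scenario not in tbl:
        valid = ", ".join(sorted(tbl))
        raise LookupError_(
            f"unknown accident scenario {scenario!r}; valid: {valid}")
    return tbl[scenario]


def combined_leakage_conditional(
    scenarios: Iterable[str], table: Mapping[str, float] | None = None,
) -> float:
    """Sum of P^B over a user-selected subset of accident scenarios.

    Accident types are mutually exclusive, so their conditional leakage
    probabilities add.
    """
    total = sum(lookup_leakage_conditional(s, table) for s in scenarios)
    if not 0.0 <= total <= 1.0:
        raise ValueError(f"combined conditional probability {total} outside [0, 1]")
    return total


def leakage_rate(p_a: float, p_b: float) -> float:
    """P^C = P^A x P^B, in accidents per million vehicle-km."""
    if p_a <= 0:
        raise ValueError(f"accident rate P^A must be > 0, got {p_a}")
    if not 0.0 <= p_b <= 1.0:
        raise ValueError(f"conditional probability P^B must be in [0, 1], got {p_b}")
    return p_a * p_b


def segment_leakage_probability(
    segment: RoadSegment,
    t: int,
    p_b: float | None = None,
    *,
    rate_table: Mapping[tuple[str, str], float] | None = None,
    use_length_squared: bool = False,
) -> float:
    """Leakage accident probability P_ij(t) for one segment-period.

    P^A is looked up from the segment's (region, road_type); ``p_b`` defaults
    to the "overturned on the road" conditional. The result is not clamped to
    <= 1 (realistic values are ~1e-6..1e-4); a warning is emitted if it
    exceeds 1.
    """
    if not 0 <= t < N_PERIODS:
        raise ValueError(f"period t must be in 0..{N_PERIODS - 1}, got {t}")
    if p_b is None:
        p_b = lookup_leakage_conditional(DEFAULT_ACCIDENT_SCENARIO)
    p_a = lookup_truck_accident_rate(segment.region, segment.road_type, rate_table)
    p_c = leakage_rate(p_a, p_b)
    length_factor = segment.length_km ** 2 if use_length_squared \
        else segment.length_km / 2.0
    p = 1e-6 * p_c * segment.vehicle_density[t] * length_factor
    if p > 1.0:
        warnings.warn(
            f"segment {segment.label} period {t}: leakage probability {p:.3g} "
            "exceeds 1; inputs are outside the model's intended range",
            stacklevel=2)
    return p


def load_rate_table(path: str) -> dict[tuple[str, str], float]:
    """Read a (region, road_type, rate) CSV override for the accident rates."""
    out: dict[tuple[str, str], float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[(row["region"], row["road_type"])] = float(row["rate"])
    if not out:
        raise ValueError(f"empty accident-rate table: {path}")
    for key, rate in out.items():
        if rate <= 0:
            raise ValueError(f"accident rate for {key} must be > 0, got {rate}")
    return out


def load_leakage_table(path: str) -> dict[str, float]:
    """Read a (scenario, probability) CSV override for the leakage table."""
    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["scenario"]] = float(row["probability"])
    if not out:
        raise ValueError(f"empty leakage table: {path}")
    for key, p in out.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"conditional probability for {key!r} outside [0, 1]")
    return out
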