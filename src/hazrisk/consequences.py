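"""Monetized accident consequences.

Population exposure: each AEGL ring area times the local population density
gives the exposed headcount; each exposed person incurs cost type v
(evacuation, inspection, medical, casualties) with probability alpha_uv(t),
at unit cost F_v:

    C_pop(t) = sum_u sum_v S_u(t) * T(t) * alpha_uv(t) * F_v

Environmental pollution: each medium's polluted volume times per-m^3 unit
costs for emergency disposal, monitoring and remediation:

    C_env(t) = sum_r sum_w V_r(t) * F_rw

Currency is an opaque unit (CNY in typical use); both consequences are
homogeneous of degree 1 in their cost tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import N_PERIODS
from .plume import ExposureZones
from .water import PollutionVolumes

__all__ = [
    "PopulationCostTable",
    "CostIncidence",
    "EnvCostTable",
    "DEFAULT_POP_COSTS",
    "DEFAULT_ENV_COSTS",
    "DEFAULT_INCIDENCE",
    "population_consequence",
    "environmental_consequence",
]

COST_TYPES = ("evacuation", "inspection", "medical", "casualties")
ENV_COST_TYPES = ("emergency_disposal", "monitoring", "remediation")


@dataclass(frozen=True)
class PopulationCostTable:
    """Per-person unit costs F_v for v = evacuation, inspection, medical,
    casualties (currency/person)."""

    values: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.values) != 4 or any(v < 0 for v in self.values):
            raise ValueError(f"need 4 non-negative population costs, got {self.values}")


@dataclass(frozen=True)
class CostIncidence:
    """alpha_uv(t): probability that a person in zone u incurs cost type v
    at period t, as a (3 zones x 4 cost types x 24 periods) array.

    Zone u=0 is the outermost (AEGL-1, mildest) ring and u=2 the innermost
    (AEGL-3, life-threatening) disc.
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=float)
        if arr.shape != (3, 4, N_PERIODS):
            raise ValueError(
                f"incidence table must have shape (3, 4, {N_PERIODS}), got {arr.shape}")
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("incidence probabilities must lie in [0, 1]")
        object.__setattr__(self, "table", arr)

    @classmethod
    def constant(cls, alpha_3x4) -> "CostIncidence":
        """Time-invariant incidence from a 3x4 array."""
        a = np.asarray(alpha_3x4, dtype=float)
        return cls(np.repeat(a[:, :, None], N_PERIODS, axis=2))


@dataclass(frozen=True)
class EnvCostTable:
    """F_rw: per-m^3 treatment costs, rows r = air/groundwater/lake/river,
    columns w = emergency disposal / monitoring / remediation."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (4, 3):
            raise ValueError(f"env cost table must be 4x3, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("environmental unit costs must be >= 0")
        object.__setattr__(self, "values", arr)


# Illustrative defaults (CNY). The incidence rises with zone severity:
# nearly everyone in the innermost (AEGL-3) zone needs medical care while
# the outer (AEGL-1) ring mostly incurs evacuation/inspection costs. These
# are documentation-level placeholders, not calibrated values.
DEFAULT_POP_COSTS = PopulationCostTable(values=(500.0, 300.0, 5000.0, 1.5e6))

DEFAULT_INCIDENCE = CostIncidence.constant([
    # evacuation, inspection, medical, casualties
    [0.50, 0.30, 0.05, 0.001],   # zone 1: AEGL-1 ring
    [0.90, 0.60, 0.30, 0.010],   # zone 2: AEGL-2 ring
    [1.00, 0.90, 0.80, 0.200],   # zone 3: AEGL-3 disc
])

DEFAULT_ENV_COSTS = EnvCostTable(values=np.array([
    # emergency disposal, monitoring, remediation (CNY/m^3)
    [0.02, 0.01, 0.02],    # air
    [5.00, 2.00, 20.00],   # groundwater
    [2.00, 1.00, 8.00],    # lake
    [2.00, 1.00, 6.00],    # river
]))


def population_consequence(
    zones: ExposureZones,
    population_density: float,
    alpha: CostIncidence,
    costs: PopulationCostTable,
    t: int,
) -> float:
    """Total monetized population-exposure consequence C_pop(t).

    ``population_density`` is T_ij(t) in persons/m^2; linear in it and in
    every cost entry.
    """
    if population_density < 0:
        raise ValueError("population density must be >= 0")
    s = np.asarray(zones.areas)                       # (3,)
    a = alpha.table[:, :, t]                          # (3, 4)
    f = np.asarray(costs.values)                      # (4,)
    return float(population_density * np.sum(s[:, None] * a * f[None, :]))


def environmental_consequence(
    volumes: PollutionVolumes, costs: EnvCostTable,
) -> float:
    """Total monetized environmental-pollution consequence C_env(t);
    absent media contribute zero through their zero volumes."""
    v = np.asarray(volumes.volumes)                   # (4,)
    return float(np.sum(v[:, None] * costs.values))
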