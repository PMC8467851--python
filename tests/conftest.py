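import math

import pytest

from hazrisk import (
    GeneratorConfig,
    ReleaseScenario,
    StabilityParameters,
    default_scenario,
    generate_network,
)


def make_scenario(
    *,
    release_rate=math.pi,
    aegl=(0.25, 0.5, 1.0),
    water=(1.0, 1.0, 1.0),
    total=1e9,
    elapsed=(1e4, 1e4, 1e4),
    friction=0.1,
    height=0.0,
    chemical="testgas",
):
    """Scenario builder with free parameters; the air limit is tied to AEGL-2."""
    return ReleaseScenario(
        chemical_name=chemical,
        total_amount_mg=total,
        release_rate_mg_s=release_rate,
        source_height_m=height,
        aegl_thresholds=tuple(aegl),
        env_thresholds=(aegl[1], *water),
        elapsed_times_s=tuple(elapsed),
        friction_velocity=friction,
    )


@pytest.fixture(scope="session")
def unit_stability():
    """sigma_y = sigma_z = sqrt(x): every closed form collapses to simple
    arithmetic."""
    return StabilityParameters(a=1.0, b=1.0, c=0.5, d=0.5)


@pytest.fixture(scope="session")
def simple_scenario():
    """Release with Q^Hazard = pi so the plume bracket is 1/(v*C)."""
    return make_scenario()


@pytest.fixture(scope="session")
def study_network():
    """The default 38-node / 52-arc synthetic study network."""
    return generate_network(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def study_scenario():
    """6 t gaseous ammonia released over 600 s."""
    return default_scenario()
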