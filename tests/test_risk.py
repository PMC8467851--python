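import math

import pytest
from hypothesis import given, settings, strategies as st

from hazrisk import (
    AssessmentConfig,
    RoadNetwork,
    TimeProfile,
    assess_network,
    assess_segment,
    environment_ratio,
    environmental_risk,
    population_ratio,
    population_risk,
    preference_parameter,
    route_risk,
    rank_segments,
)
from hazrisk.risk import PREFERENCE_LEVELS

from conftest import make_scenario
from test_consequences import volumes, zones_with_areas
from test_network import minimal_segment


class TestPopulationRatio:
    def test_hand_computed_unit_ratio(self):
        # sum S = 1.2e6 m^2, L = 2 km, d = 600 m: 1.2e6/(1000*2*600) = 1
        zones = zones_with_areas(1.0e6, 1.5e5, 5.0e4)
        assert population_ratio(zones, 0.01, 2.0, 600.0) == \
            pytest.approx(1.0, rel=1e-12)

    def test_independent_of_density(self):
        zones = zones_with_areas(5e5, 1e5, 1e4)
        r1 = population_ratio(zones, 0.001, 1.5)
        r2 = population_ratio(zones, 0.5, 1.5)
        assert r1 == pytest.approx(r2, rel=1e-14)

    def test_zero_density_is_undefined(self):
        zones = zones_with_areas(1e5, 0.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            population_ratio(zones, 0.0, 1.0)


class TestEnvironmentRatio:
    def test_definition_at_capacity(self):
        vols = volumes(v_air=100.0)
        thresholds = (2.0, 1.0, 1.0, 1.0)
        assert environment_ratio(200.0, vols, thresholds) == \
            pytest.approx(1.0, rel=1e-14)

    def test_arithmetic(self):
        vols = volumes(v_air=100.0)
        assert environment_ratio(500.0, vols, (2.0, 1.0, 1.0, 1.0)) == \
            pytest.approx(2.5, rel=1e-14)

    def test_linear_in_release_amount(self):
        vols = volumes(v_air=50.0, v_gw=20.0)
        thr = (1.0, 3.0, 1.0, 1.0)
        assert environment_ratio(2e6, vols, thr) == pytest.approx(
            2.0 * environment_ratio(1e6, vols, thr), rel=1e-14)

    def test_zero_capacity_is_undefined(self):
        with pytest.raises(ValueError, match="capacity"):
            environment_ratio(100.0, volumes(), (1.0, 1.0, 1.0, 1.0))


class TestPreferenceParameter:
    @pytest.mark.parametrize("p,q", [
        (0.0, 0.9),
        (0.3, 0.9),
        (0.5, 0.9),     # bracket boundary: 0 < p <= 0.5
        (0.50001, 0.95),
        (0.999, 0.95),
        (1.0, 1.0),     # exactly at capacity
        (1.2, 1.05),
        (1.5, 1.05),    # bracket boundary: 1 < p <= 1.5
        (1.50001, 1.1),
        (2.0, 1.1),
        (100.0, 1.1),
    ])
    def test_piecewise_brackets(self, p, q):
        assert preference_parameter(p) == q

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            preference_parameter(-0.1)

    @settings(derandomize=True, max_examples=300)
    @given(p=st.floats(0.0, 10.0), delta=st.floats(0.0, 5.0))
    def test_nondecreasing_step_function(self, p, delta):
        assert preference_parameter(p + delta) >= preference_parameter(p)
        assert preference_parameter(p) in PREFERENCE_LEVELS

    def test_crosses_one_exactly_at_capacity(self):
        assert preference_parameter(1.0 - 1e-12) < 1.0
        assert preference_parameter(1.0) == 1.0
        assert preference_parameter(1.0 + 1e-12) > 1.0


class TestRiskScores:
    def test_traditional_risk_at_unit_exponent(self):
        assert population_risk(1e-4, 2.5e6, 1.0) == \
            pytest.approx(1e-4 * 2.5e6, rel=1e-12)

    def test_zero_probability_and_zero_consequence(self):
        assert population_risk(0.0, 1e9, 1.1) == 0.0
        assert population_risk(1e-3, 0.0, 0.9) == 0.0

    def test_log_domain_arithmetic(self):
        # 1e-4 * (1e6)^1.1 = 1e-4 * 10^6.6
        got = population_risk(1e-4, 1e6, 1.1)
        assert got == pytest.approx(1e-4 * 10 ** 6.6, rel=1e-12)

    def test_environmental_oracle(self):
        # 2e-5 * (5e5)^0.9, checked against an independent log evaluation
        got = environmental_risk(2e-5, 5e5, 0.9)
        assert got == pytest.approx(2e-5 * math.exp(0.9 * math.log(5e5)),
                                    rel=1e-13)

    def test_monotone_in_consequence(self):
        for q in PREFERENCE_LEVELS:
            r1 = environmental_risk(1e-4, 1e5, q)
            r2 = environmental_risk(1e-4, 2e5, q)
            assert r2 > r1

    def test_linear_in_probability(self):
        assert population_risk(2e-4, 3e6, 1.05) == pytest.approx(
            2.0 * population_risk(1e-4, 3e6, 1.05), rel=1e-13)


def full_segment(**overrides):
    from hazrisk import GroundwaterAttributes, LakeAttributes, \
        RiverAttributes, WaterAttributes
    water = WaterAttributes(
        groundwater=GroundwaterAttributes(
            flow_profile=TimeProfile.constant(1e-4),
            depth=5.0, wet_cross_section=10.0),
        lake=LakeAttributes(depth=2.0, relation="alongside"),
        river=RiverAttributes(flow_profile=TimeProfile.constant(0.1),
                              depth=2.0, width=50.0, relation="crossing"),
    )
    kw = dict(water=water, wind_speed=TimeProfile.constant(1.0))
    kw.update(overrides)
    return minimal_segment(**kw)


class TestAssessSegment:
    def test_zero_traffic_zeroes_both_risks(self, unit_stability):
        seg = full_segment(vehicle_density=TimeProfile.constant(0.0))
        rec = assess_segment(seg, make_scenario(), unit_stability, None, 0)
        assert rec.probability == 0.0
        assert rec.er_pop == 0.0 and rec.er_env == 0.0
        assert rec.c_pop > 0  # consequences remain

    def test_higher_wind_period_has_lower_consequences(self, unit_stability):
        wind = [1.0] * 24
        wind[6] = 4.0
        seg = full_segment(wind_speed=TimeProfile(tuple(wind)))
        sc = make_scenario()
        calm = assess_segment(seg, sc, unit_stability, None, 0)
        windy = assess_segment(seg, sc, unit_stability, None, 6)
        assert windy.c_pop < calm.c_pop
        assert windy.c_env < calm.c_env

    def test_zero_population_short_circuits_ratio(self, unit_stability):
        seg = full_segment(population_density=TimeProfile.constant(0.0))
        rec = assess_segment(seg, make_scenario(), unit_stability, None, 0)
        assert rec.c_pop == 0.0 and rec.er_pop == 0.0
        assert rec.p_pop == 0.0 and rec.q_pop == 0.9

    def test_end_to_end_hand_composition(self, unit_stability):
        """The assessed record equals the chained hand computation built
        from plain arithmetic."""
        sc = make_scenario(total=1e9, water=(1.0, 1.0, 1.0),
                           elapsed=(1e4, 1e4, 1e4), friction=0.1,
                           release_rate=math.pi)
        seg = full_segment()
        cfg = AssessmentConfig()
        rec = assess_segment(seg, sc, unit_stability, cfg, 0)

        # probability: 1e-6 * 5.38 * 0.375 * 50 * 2/2
        p = 1e-6 * 5.38 * 0.375 * 50.0 * 1.0
        assert rec.probability == pytest.approx(p, rel=1e-12)

        # zones: unit bracket -> radii (4, 2, 1)
        s_areas = (math.pi * 12.0, math.pi * 3.0, math.pi * 1.0)
        alpha = cfg.incidence.table[:, :, 0]
        f = cfg.pop_costs.values
        c_pop = sum(s_areas[u] * 0.01 * alpha[u, v] * f[v]
                    for u in range(3) for v in range(4))
        assert rec.c_pop == pytest.approx(c_pop, rel=1e-9)

        # volumes: air hemisphere on r=2 plus the three water oracles
        v_air = (2.0 / 3.0) * math.pi * 8.0
        disp_gw = math.sqrt(5.0 * 0.1 * 1e4)
        r_gw = 1e-4 * 1e4 + disp_gw * math.log(
            1e9 / (10.0 * math.sqrt(math.pi * 5.0 * 0.1 * 1e4)))
        v_gw = (2.0 / 3.0) * math.pi * r_gw ** 3
        disp_sw = math.sqrt(0.58 * 2.0 * 0.1 * 1e4)
        r_lk = disp_sw * math.log(1e9 / (0.58 * math.pi * 4.0 * 0.1 * 1e4))
        v_lk = (1.0 / 3.0) * math.pi * r_lk ** 3
        factor = 2.0 + math.exp(-2500.0 / (0.145 * 2.0 * 0.1 * 1e4))
        r_rv = 0.1 * 1e4 + disp_sw * math.log(
            1e9 * factor / (0.58 * math.pi * 4.0 * 0.1 * 1e4))
        v_rv = (2.0 / 3.0) * math.pi * r_rv ** 3
        vols = (v_air, v_gw, v_lk, v_rv)
        assert rec.volumes.volumes == pytest.approx(vols, rel=1e-9)

        c_env = sum(vols[r] * cfg.env_costs.values[r, w]
                    for r in range(4) for w in range(3))
        assert rec.c_env == pytest.approx(c_env, rel=1e-9)

        p_pop = sum(s_areas) / (1e3 * 2.0 * 600.0)
        p_env = 1e9 / (vols[0] * 0.5 + vols[1] + vols[2] + vols[3])
        assert rec.p_pop == pytest.approx(p_pop, rel=1e-9)
        assert rec.p_env == pytest.approx(p_env, rel=1e-9)

        q_pop = preference_parameter(p_pop)
        q_env = preference_parameter(p_env)
        assert rec.er_pop == pytest.approx(
            p * math.exp(q_pop * math.log(c_pop)), rel=1e-9)
        assert rec.er_env == pytest.approx(
            p * math.exp(q_env * math.log(c_env)), rel=1e-9)


class TestAssessNetwork:
    def test_single_segment_gives_24_records(self, unit_stability):
        net = RoadNetwork(nodes=frozenset({"1", "2"}),
                          segments=(full_segment(),))
        df = assess_network(net, make_scenario(), unit_stability)
        assert len(df) == 24
        assert sorted(df["period"]) == list(range(24))

    def test_study_network_record_count(self, study_network, study_scenario):
        from hazrisk import get_stability
        df = assess_network(study_network, study_scenario, get_stability("D"))
        assert len(df) == 52 * 24

    def test_segments_are_independent(self, unit_stability):
        """Removing a segment leaves the others' records unchanged."""
        a = full_segment(segment_id=("1", "2"))
        b = full_segment(segment_id=("2", "3"),
                         wind_speed=TimeProfile.constant(2.0))
        sc = make_scenario()
        both = assess_network(
            RoadNetwork(nodes=frozenset("123"), segments=(a, b)),
            sc, unit_stability)
        alone = assess_network(
            RoadNetwork(nodes=frozenset("12"), segments=(a,)),
            sc, unit_stability)
        merged = both[both["node_j"] == "2"].reset_index(drop=True)
        assert merged.equals(alone)


class TestRouteRisk:
    def make_records(self, unit_stability):
        a = full_segment(segment_id=("1", "2"))
        b = full_segment(segment_id=("2", "3"),
                         wind_speed=TimeProfile.constant(2.0))
        net = RoadNetwork(nodes=frozenset("123"), segments=(a, b))
        return assess_network(net, make_scenario(), unit_stability)

    def test_empty_route(self, unit_stability):
        assert route_risk(self.make_records(unit_stability), [], 0) == (0.0, 0.0)

    def test_single_segment_route(self, unit_stability):
        df = self.make_records(unit_stability)
        pop, env = route_risk(df, [("1", "2")], 3)
        row = df[(df["node_i"] == "1") & (df["period"] == 3)].iloc[0]
        assert pop == row["er_pop"] and env == row["er_env"]

    def test_concatenation_additivity(self, unit_stability):
        df = self.make_records(unit_stability)
        whole = route_risk(df, [("1", "2"), ("2", "3")], 5)
        parts = tuple(
            x + y for x, y in zip(route_risk(df, [("1", "2")], 5),
                                  route_risk(df, [("2", "3")], 5)))
        assert whole == pytest.approx(parts, rel=1e-14)

    def test_unknown_segment(self, unit_stability):
        with pytest.raises(KeyError):
            route_risk(self.make_records(unit_stability), [("7", "9")], 0)


def test_ranking_by_risk_matches_ranking_by_powered_consequence(unit_stability):
    """At equal probability, ordering segments by ER or by C^q coincides."""
    segs = tuple(
        full_segment(segment_id=(str(i), str(i + 1)),
                     wind_speed=TimeProfile.constant(w))
        for i, w in enumerate([0.5, 1.0, 2.0, 4.0], start=1))
    net = RoadNetwork(nodes=frozenset(str(i) for i in range(1, 6)),
                      segments=segs)
    df = assess_network(net, make_scenario(), unit_stability)
    at_noon = df[df["period"] == 12].copy()
    assert at_noon["probability"].nunique() == 1
    at_noon["cq"] = at_noon["c_pop"] ** at_noon["q_pop"]
    by_er = at_noon.sort_values("er_pop")["node_i"].tolist()
    by_cq = at_noon.sort_values("cq")["node_i"].tolist()
    assert by_er == by_cq
    ranked = rank_segments(df, by="er_pop")
    assert len(ranked) == 4 and ranked["max_value"].is_monotonic_decreasing
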