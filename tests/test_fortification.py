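"""Fortification increments, year gating, additivity, refusal of oil."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vitdsupply import (CommodityMap, ConfigurationError, FortificationPolicy,
                        ValidationError, apply_policies, flour_increment,
                        load_policies, milk_increment, policy_increment)

from conftest import make_table


@pytest.mark.parametrize("g_day,level,cov,expected", [
    (300.0, 10.0, 1.0, 3.0),
    (123.0, 50.0, 0.0, 0.0),
    (250.0, 20.0, 0.5, 2.5),
])
def test_flour_increment_hand_values(g_day, level, cov, expected):
    assert flour_increment(g_day, level, cov) == pytest.approx(expected)


def test_flour_increment_rejects_coverage_above_one():
    with pytest.raises(ValidationError):
        flour_increment(100.0, 10.0, 1.2)


@pytest.mark.parametrize("g_day,level,cov,share,expected", [
    (500.0, 10.0, 1.0, 0.6, 3.0),   # 0.5 L × 0.6 × 10
    (500.0, 10.0, 1.0, 0.0, 0.0),
])
def test_milk_increment_hand_values(g_day, level, cov, share, expected):
    assert milk_increment(g_day, level, cov, share) == pytest.approx(expected)


def test_milk_policy_requires_product_share():
    with pytest.raises(ValidationError):
        FortificationPolicy("X", "milk", 10.0, 1.0, 2016)


def test_oil_refused_without_retention():
    policy = FortificationPolicy("X", "oil", 10.0, 1.0, 2016)
    with pytest.raises(ConfigurationError, match="retention"):
        policy_increment(policy, 30.0)
    # explicit retention factor unlocks it
    assert policy_increment(policy, 30.0, oil_retention=0.7) == pytest.approx(
        30.0 * 10.0 / 1000.0 * 0.7)


@pytest.fixture
def flat_table():
    """Flat 200 g/d wheat for 2014–2017."""
    return make_table([("X", y, 2511, 200.0) for y in range(2014, 2018)])


@pytest.fixture
def wheat_map():
    return CommodityMap({2511: "wheat"})


def test_apply_policies_year_gating(flat_table, wheat_map):
    baseline = {y: 1.0 for y in range(2014, 2018)}
    policy = FortificationPolicy("X", "wheat_flour", 10.0, 1.0, 2016)
    fortified = apply_policies(baseline, [policy], flat_table, wheat_map, "X")
    assert fortified[2014] == fortified[2015] == 1.0
    assert fortified[2016] == fortified[2017] == pytest.approx(3.0)


def test_no_policies_is_identity(flat_table, wheat_map):
    baseline = {y: 2.0 + 0.1 * y for y in range(2014, 2018)}
    assert apply_policies(baseline, [], flat_table, wheat_map, "X") == pytest.approx(baseline)


@pytest.mark.parametrize("policy", [
    FortificationPolicy("X", "wheat_flour", 0.0, 1.0, 2014),
    FortificationPolicy("X", "wheat_flour", 10.0, 0.0, 2014),
])
def test_zero_level_or_coverage_is_noop(policy, flat_table, wheat_map):
    baseline = {y: 1.5 for y in range(2014, 2018)}
    assert apply_policies(baseline, [policy], flat_table,
                          wheat_map, "X") == pytest.approx(baseline)


def test_policy_for_absent_country_skipped_with_warning(flat_table, wheat_map,
                                                        caplog):
    baseline = {2014: 1.0}
    policy = FortificationPolicy("NOPE", "wheat_flour", 10.0, 1.0, 2014)
    with caplog.at_level("WARNING"):
        out = apply_policies(baseline, [policy], flat_table, wheat_map, "NOPE")
    assert out == baseline
    assert any("skipped" in r.message for r in caplog.records)


@given(level1=st.floats(0, 50), level2=st.floats(0, 50),
       share=st.floats(0, 1))
def test_increments_are_additive_across_vehicles(level1, level2, share):
    table = make_table([("X", 2015, 2511, 200.0), ("X", 2015, 2848, 400.0)])
    cmap = CommodityMap({2511: "wheat", 2848: "milk"})
    baseline = {2015: 2.0}
    p_wheat = FortificationPolicy("X", "wheat_flour", level1, 1.0, 2015)
    p_milk = FortificationPolicy("X", "milk", level2, 1.0, 2015,
                                 milk_product_share=share)
    both = apply_policies(baseline, [p_wheat, p_milk], table, cmap, "X")
    only_w = apply_policies(baseline, [p_wheat], table, cmap, "X")
    only_m = apply_policies(baseline, [p_milk], table, cmap, "X")
    assert both[2015] == pytest.approx(
        only_w[2015] + only_m[2015] - baseline[2015], rel=1e-12, abs=1e-9)
    assert both[2015] >= baseline[2015]


def test_load_policies_csv_and_yaml(tmp_path):
    csv = tmp_path / "pol.csv"
    csv.write_text(
        "country_code,vehicle,level,level_unit,coverage,start_year,basis,"
        "milk_product_share\n"
        "JOR,wheat_flour,20.0,ug_per_kg,1.0,2002,mandatory,\n"
        "CAN,milk,8.8,ug_per_L,1.0,1975,mandatory,0.65\n")
    pols = load_policies(csv)
    assert [p.vehicle for p in pols] == ["wheat_flour", "milk"]
    assert pols[1].milk_product_share == pytest.approx(0.65)

    yml = tmp_path / "pol.yaml"
    yml.write_text(
        "policies:\n"
        "  - {country_code: FIN, vehicle: milk, level: 10.0, coverage: 1.0,\n"
        "     start_year: 2003, basis: voluntary, milk_product_share: 0.7}\n")
    (pol,) = load_policies(yml)
    assert pol.basis == "voluntary" and pol.level == 10.0
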