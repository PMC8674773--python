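"""Supply estimation: hand-summed examples, oracle equivalence, properties."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vitdsupply import (BioactivityOptions, CommodityMap, CompositionEntry,
                        CompositionTable, NotFoundError, contribution_shares,
                        country_year_supply, estimate_period, ohd_increment,
                        period_estimate, yearly_supply)

from conftest import make_table


def brute_force_supply(table, country, year, comp, mapping, opts):
    """Independent oracle: plain loop over raw records, no grouping."""
    total = 0.0
    for _, row in table.records.iterrows():
        if row["country_code"] != country or row["year"] != year:
            continue
        group = mapping.resolve(row["commodity_code"])
        if group is None or group not in comp:
            continue
        entry = comp[group]
        content = entry.vitd3_per_100g
        if opts.include_ohd:
            content += opts.bioactivity_factor * entry.ohd3_per_100g
        total += row["g_per_day"] * content / 100.0
    return total


def test_single_commodity_hand_value(mapping):
    comp = CompositionTable.from_entries(
        [CompositionEntry("pelagic_fish", "Fish", 2.0, 0.0)])
    table = make_table([("AAA", 2015, "FISH", 100.0)])
    assert country_year_supply(table, "AAA", 2015, comp, mapping) == pytest.approx(2.0)


def test_mixed_basket_hand_sum(simple_table, comp, mapping):
    # 50*8/100 + 0 + 30*(3.0 + 5*0.2)/100 = 4.0 + 0 + 1.2
    got = country_year_supply(simple_table, "AAA", 2015, comp, mapping,
                              BioactivityOptions(True, 5.0))
    assert got == pytest.approx(5.2)
    # excluding 25(OH)D: 4.0 + 0.9
    got = country_year_supply(simple_table, "AAA", 2015, comp, mapping,
                              BioactivityOptions(include_ohd=False))
    assert got == pytest.approx(4.9)


def test_absent_country_year_is_not_zero(simple_table, comp, mapping):
    with pytest.raises(NotFoundError):
        country_year_supply(simple_table, "AAA", 1999, comp, mapping)
    with pytest.raises(NotFoundError):
        country_year_supply(simple_table, "ZZZ", 2015, comp, mapping)


@pytest.mark.parametrize("yearly,expected_mean,expected_sd", [
    ({2014: 4.0, 2015: 4.0, 2016: 4.0, 2017: 4.0}, 4.0, 0.0),
    ({2014: 3.0, 2015: 5.0}, 4.0, 1.4142135623730951),
])
def test_period_estimate_mean_and_sample_sd(yearly, expected_mean, expected_sd):
    est = period_estimate(yearly, (2014, 2017))
    assert est.mean_ug_day == pytest.approx(expected_mean)
    assert est.sd_ug_day == pytest.approx(expected_sd)
    assert est.n_years == len(yearly)


def test_period_estimate_single_year_sd_zero():
    est = period_estimate({2016: 2.5}, (2014, 2017))
    assert est.sd_ug_day == 0.0 and est.n_years == 1


def test_period_estimate_no_overlap_errors():
    with pytest.raises(NotFoundError):
        period_estimate({2010: 1.0}, (2014, 2017))


def test_contribution_shares_hand_ratios(simple_table, comp, mapping):
    bd = contribution_shares(simple_table, "AAA", (2015, 2015), comp, mapping)
    assert bd.shares["pelagic_fish"] == pytest.approx(4.0 / 5.2)
    assert bd.shares["eggs"] == pytest.approx(1.2 / 5.2)
    assert bd.shares.get("wheat", 0.0) == 0.0
    assert sum(bd.shares.values()) == pytest.approx(1.0, abs=1e-9)


def test_contribution_shares_degenerate_zero_total(mapping):
    comp = CompositionTable.from_entries(
        [CompositionEntry("wheat", "Wheat", 0.0, 0.0)])
    table = make_table([("AAA", 2015, "WHEAT", 300.0)])
    bd = contribution_shares(table, "AAA", (2015, 2015), comp, mapping)
    assert bd.zero_total and bd.shares == {}


def test_ohd_increment_zero_when_no_ohd_content(simple_table, mapping):
    comp = CompositionTable.from_entries([
        CompositionEntry("pelagic_fish", "Fish", 8.0, 0.0),
        CompositionEntry("eggs", "Eggs", 3.0, 0.0),
        CompositionEntry("wheat", "Wheat", 0.0, 0.0)])
    assert ohd_increment(simple_table, "AAA", (2015, 2015),
                         comp, mapping) == pytest.approx(0.0)


@st.composite
def random_tables(draw):
    groups = ["g1", "g2", "g3"]
    entries = [CompositionEntry(g, g, draw(st.floats(0, 10)),
                                draw(st.floats(0, 1))) for g in groups]
    mapping = CommodityMap({f"C{i}": draw(st.sampled_from(groups + [None]))
                            for i in range(5)})
    records = []
    for country in ["AAA", "BBB"]:
        for year in [2014, 2015]:
            for i in range(5):
                records.append((country, year, f"C{i}",
                                draw(st.floats(0, 500))))
    return (make_table(records), CompositionTable.from_entries(entries),
            mapping)


@given(data=random_tables(),
       include_ohd=st.booleans())
def test_matches_brute_force_oracle(data, include_ohd):
    table, comp, mapping = data
    opts = BioactivityOptions(include_ohd, 5.0)
    for country in ["AAA", "BBB"]:
        for year in [2014, 2015]:
            fast = country_year_supply(table, country, year, comp, mapping, opts)
            slow = brute_force_supply(table, country, year, comp, mapping, opts)
            assert fast == pytest.approx(slow, abs=1e-9)


@given(data=random_tables(), scale=st.floats(0.1, 10))
def test_supply_is_linear_in_composition_and_mass(data, scale):
    table, comp, mapping = data
    base = country_year_supply(table, "AAA", 2014, comp, mapping)
    scaled_comp = CompositionTable.from_entries([
        CompositionEntry(e.group_id, e.group_name,
                         e.vitd3_per_100g * scale, e.ohd3_per_100g * scale)
        for e in comp.entries.values()])
    assert country_year_supply(table, "AAA", 2014, scaled_comp,
                               mapping) == pytest.approx(scale * base, rel=1e-9,
                                                         abs=1e-9)
    heavier = table.records.copy()
    heavier["g_per_day"] *= scale
    table2 = make_table(list(zip(heavier.country_code, heavier.year,
                                 heavier.commodity_code, heavier.g_per_day)))
    assert country_year_supply(table2, "AAA", 2014, comp,
                               mapping) == pytest.approx(scale * base, rel=1e-9,
                                                         abs=1e-9)


@given(data=random_tables())
def test_including_ohd_never_decreases_supply(data):
    table, comp, mapping = data
    inc = estimate_period(table, "AAA", (2014, 2015), comp, mapping,
                          BioactivityOptions(True)).mean_ug_day
    exc = estimate_period(table, "AAA", (2014, 2015), comp, mapping,
                          BioactivityOptions(False)).mean_ug_day
    assert inc >= exc - 1e-12
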