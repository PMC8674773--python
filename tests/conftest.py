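import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vitdsupply import (CommodityMap, CompositionEntry, CompositionTable,
                        SupplyTable)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_table(records, dialect="new_fbs"):
    """Build a SupplyTable straight from (country, year, code, g_day) rows."""
    df = pd.DataFrame(records, columns=["country_code", "year",
                                        "commodity_code", "g_per_day"])
    df["country_name"] = df["country_code"].astype(str)
    df["commodity_name"] = df["commodity_code"].astype(str)
    return SupplyTable(records=df, dialect=dialect)


@pytest.fixture
def comp():
    """Three-group table used by the hand-computed examples."""
    return CompositionTable.from_entries([
        CompositionEntry("pelagic_fish", "Pelagic fish", 8.0, 0.0),
        CompositionEntry("eggs", "Eggs", 3.0, 0.2),
        CompositionEntry("wheat", "Wheat", 0.0, 0.0),
    ])


@pytest.fixture
def mapping():
    return CommodityMap({"FISH": "pelagic_fish", "EGGS": "eggs",
                         "WHEAT": "wheat", "ROOTS": None})


@pytest.fixture
def simple_table():
    """One country, one year: 50 g/d fish + 200 g/d wheat + 30 g/d eggs."""
    return make_table([
        ("AAA", 2015, "FISH", 50.0),
        ("AAA", 2015, "WHEAT", 200.0),
        ("AAA", 2015, "EGGS", 30.0),
    ])
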