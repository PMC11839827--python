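import math

import pytest
from hypothesis import given, strategies as st

from hrucost.unit_costs import (
    MissingPriceError,
    PriceIndexError,
    PriceIndexSeries,
    Unit,
    UnitCost,
    UnitCostTable,
    adjust_price,
)

REGISTRY_ITEMS = [
    "rivaroxaban_day",
    "enoxaparin_day",
    "tinzaparin_day",
    "fondaparinux_day",
    "hospital_day",
    "chest_xray",
    "ct",
    "mrt",
    "endoscopy_bronchoscopy",
    "lung_scintigraphy",
    "echocardiography",
    "compression_ultrasound",
    "rehab_day",
    "help_visit",
    "breathing_training",
    "compression_stockings",
    "physiotherapy",
    "productivity_day",
]


@pytest.mark.parametrize(
    "item_id,value,unit",
    [
        ("rivaroxaban_day", 3.10, Unit.PER_DAY),
        ("hospital_day", 658.27, Unit.PER_DAY),
        ("lung_scintigraphy", 44.61, Unit.PER_EXAMINATION),
        ("ct", 65.19, Unit.PER_EXAMINATION),
        ("physiotherapy", 26.70, Unit.PER_ITEM),
        ("help_visit", 15.00, Unit.PER_VISIT),
        ("productivity_day", 343.95, Unit.PER_DAY_OF_ABSENCE),
    ],
)
def test_default_registry_prices(table, item_id, value, unit):
    uc = table.lookup(item_id)
    assert uc.value == pytest.approx(value, abs=1e-12)
    assert uc.unit is unit
    assert uc.price_year == 2021


def test_registry_complete_and_fee_schedule(table):
    for item in REGISTRY_ITEMS:
        table.lookup(item)  # raises on any gap
    fees = table.fee_schedule()
    assert set(fees) == {"general_practitioner", "specialist"}
    # two-tier default implies the derived study-level mean fees
    assert 0.6 * fees["general_practitioner"] + 0.4 * fees["specialist"] == pytest.approx(
        115.33, abs=0.01
    )
    assert 0.9 * fees["general_practitioner"] + 0.1 * fees["specialist"] == pytest.approx(
        76.45, abs=0.01
    )


def test_unknown_item_is_an_error_naming_the_item(table):
    with pytest.raises(MissingPriceError) as exc:
        table.lookup("leeches")
    assert "leeches" in str(exc.value)


def test_negative_price_rejected():
    with pytest.raises(ValueError):
        UnitCost("bad", -1.0, Unit.PER_DAY, 2021)


def test_yaml_round_trip(table, tmp_path):
    path = tmp_path / "prices.yaml"
    table.to_yaml(path)
    again = UnitCostTable.from_yaml(path)
    assert set(again.entries) == set(table.entries)
    assert all(again.entries[k] == table.entries[k] for k in table.entries)


class TestAdjustPrice:
    def test_identity_year(self):
        cpi = PriceIndexSeries("cpi", {2021: 107.1})
        assert adjust_price(100.0, 2021, cpi, 2021) == pytest.approx(100.0)

    def test_factor_arithmetic(self):
        cpi = PriceIndexSeries("cpi", {2020: 100.0, 2021: 103.0})
        assert adjust_price(100.0, 2020, cpi, 2021) == pytest.approx(103.0)

    def test_cross_country_fixture(self):
        # a user-supplied CPI/PPP fixture calibrated to move 422 NL-2018 EUR
        # to ~406 German 2021 EUR (series values are configuration, the
        # composed factor is what matters)
        cpi = PriceIndexSeries("cpi", {2018: 100.0, 2021: 105.21})
        ppp = 406.0 / (422.0 * 1.0521)
        assert adjust_price(422.0, 2018, cpi, 2021, ppp_factor=ppp) == pytest.approx(
            406.0, abs=0.01
        )

    def test_missing_year_and_bad_factor(self):
        cpi = PriceIndexSeries("cpi", {2020: 100.0})
        with pytest.raises(PriceIndexError):
            adjust_price(1.0, 2020, cpi, 2021)
        with pytest.raises(PriceIndexError):
            PriceIndexSeries("cpi", {2020: 0.0})
        with pytest.raises(PriceIndexError):
            adjust_price(1.0, 2020, cpi, 2020, ppp_factor=0.0)

    @given(
        value=st.floats(0.01, 1e6),
        fa=st.floats(0.5, 300.0),
        fb=st.floats(0.5, 300.0),
    )
    def test_round_trip_and_monotonicity(self, value, fa, fb):
        cpi = PriceIndexSeries("cpi", {2018: fa, 2021: fb})
        there = adjust_price(value, 2018, cpi, 2021)
        back = adjust_price(there, 2021, cpi, 2018)
        assert math.isclose(back, value, rel_tol=1e-9)
        if fb >= fa:
            assert there >= value * (1 - 1e-12)
        else:
            assert there <= value * (1 + 1e-12)
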