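import dataclasses

import numpy as np
import pytest

from _oracles import brute_force_cost
from conftest import make_record, random_record
from hrucost.cost_engine import (
    COMPONENTS,
    ambulatory_cost,
    anticoagulation_cost,
    cost_patient,
    diagnostics_cost,
    help_and_rehab_cost,
    hospitalisation_cost,
    other_medical_cost,
)
from hrucost.hru_model import (
    AmbulatoryGroup,
    Anticoagulant,
    CountWithPE,
    Employment,
    Hospitalisation,
    ProductivityLossCategory,
    RehabEpisode,
)
from hrucost.unit_costs import MissingPriceError, UnitCost, UnitCostTable


class TestComponents:
    @pytest.mark.parametrize(
        "drug,days,expected",
        [
            (Anticoagulant.RIVAROXABAN, 90, 279.00),
            (Anticoagulant.RIVAROXABAN, 0, 0.0),
            (Anticoagulant.ENOXAPARIN, 90, 1304.10),
        ],
    )
    def test_anticoagulation(self, table, drug, days, expected):
        total, attrib = anticoagulation_cost(drug, days, table)
        assert total == pytest.approx(expected, abs=1e-9)
        assert attrib == total  # index-event therapy, always attributable

    def test_hospitalisation(self, table):
        assert hospitalisation_cost([(11.66, True)], table)[0] == pytest.approx(
            7675.43, abs=0.01
        )
        assert hospitalisation_cost([], table) == (0.0, 0.0)
        total, attrib = hospitalisation_cost(
            [Hospitalisation(3, True), Hospitalisation(4, False)], table
        )
        assert total == pytest.approx(4607.89, abs=1e-9)
        assert attrib == pytest.approx(1974.81, abs=1e-9)

    def test_ambulatory(self):
        total, _ = ambulatory_cost([("gp", 16, 0)], {"gp": 115.33})
        assert total == pytest.approx(1845.28, abs=1e-9)
        assert ambulatory_cost([], {}) == (0.0, 0.0)
        total, attrib = ambulatory_cost([("gp", 2, 2)], {"gp": 76.45})
        assert total == attrib == pytest.approx(152.90, abs=1e-9)

    def test_ambulatory_unknown_specialty(self):
        with pytest.raises(MissingPriceError):
            ambulatory_cost([("homeopathy", 1, 0)], {"gp": 100.0})

    def test_diagnostics(self, table):
        assert diagnostics_cost({"ct": (1, 0)}, table)[0] == pytest.approx(65.19)
        assert diagnostics_cost({}, table) == (0.0, 0.0)
        total, attrib = diagnostics_cost(
            {"echocardiography": (1, 1), "compression_ultrasound": (1, 1)}, table
        )
        assert total == attrib == pytest.approx(35.42, abs=1e-9)

    def test_help_and_rehab(self, table):
        rec = make_record(help_visits=CountWithPE(10, 0))
        assert help_and_rehab_cost(rec, table)[0] == pytest.approx(150.00)
        rec = make_record(rehab_inpatient=RehabEpisode(38.5, False))
        assert help_and_rehab_cost(rec, table)[0] == pytest.approx(5207.125, abs=1e-9)
        assert help_and_rehab_cost(make_record(), table) == (0.0, 0.0)

    def test_other_medical(self, table):
        assert other_medical_cost({"compression_stockings": (1, 0)}, table)[0] == 15.00
        assert other_medical_cost({}, table) == (0.0, 0.0)
        assert other_medical_cost(
            {"physiotherapy": (2, 0), "breathing_training": (1, 0)}, table
        )[0] == pytest.approx(73.40, abs=1e-9)


class TestCostPatient:
    def test_anticoagulation_only_record(self, table):
        bd = cost_patient(make_record(anticoagulation_days=90), table)
        assert bd.overall_total == pytest.approx(279.00)
        assert bd.pe_attributable_total == pytest.approx(279.00)

    def test_all_zero_record(self, table):
        bd = cost_patient(make_record(), table)
        assert bd.overall_total == 0.0

    def test_anticoagulation_plus_pe_stay(self, table):
        rec = make_record(
            anticoagulation_days=90, hospitalisations=(Hospitalisation(3, True),)
        )
        bd = cost_patient(rec, table)
        assert bd.overall_total == pytest.approx(2253.81, abs=1e-9)
        assert bd.pe_attributable_total == pytest.approx(2253.81, abs=1e-9)

    def test_breakdown_identities(self, table):
        rng = np.random.default_rng(7)
        for i in range(50):
            bd = cost_patient(random_record(rng, f"R{i}"), table)
            assert bd.overall_total == pytest.approx(
                bd.direct_total + bd.indirect_total, rel=1e-12
            )
            assert bd.pe_attributable_total <= bd.overall_total + 1e-9
            for comp in COMPONENTS:
                total, attrib = bd.components[comp]
                assert 0 <= attrib <= total + 1e-9

    def test_attribution_equality_iff_everything_flagged(self, table):
        rec = make_record(
            "F1",
            anticoagulation_days=10,
            employed_before_pe=Employment.YES,
            productivity_loss_category=ProductivityLossCategory.LE_6_WEEKS,
            ambulatory_visits=(AmbulatoryGroup("specialist", 3, 3),),
            hospitalisations=(Hospitalisation(2, True),),
            diagnostics={"ct": CountWithPE(1, 1)},
            help_visits=CountWithPE(2, 2),
            other_items={"physiotherapy": CountWithPE(1, 1)},
            other_medications_cost=12.0,
            other_medications_pe_cost=12.0,
        )
        bd = cost_patient(rec, table)
        assert bd.pe_attributable_total == pytest.approx(bd.overall_total, rel=1e-12)

    def test_additivity_of_components(self, table, fees):
        rng = np.random.default_rng(11)
        rec = random_record(rng, "A1")
        bd = cost_patient(rec, table)
        parts = {
            "anticoagulation": anticoagulation_cost(
                rec.anticoagulant, rec.anticoagulation_days, table
            ),
            "ambulatory_visits": ambulatory_cost(rec.ambulatory_visits, fees),
            "rehospitalisation": hospitalisation_cost(rec.hospitalisations, table),
            "diagnostics": diagnostics_cost(rec.diagnostics, table),
            "other_medical": other_medical_cost(rec.other_items, table),
            "formal_informal_help": help_and_rehab_cost(rec, table),
        }
        for comp, pair in parts.items():
            assert bd.components[comp] == pair

    def test_price_homogeneity(self, table, fees):
        """Scaling every unit price by lambda scales every money output by lambda."""
        lam = 1.75
        scaled = UnitCostTable(
            entries={
                k: UnitCost(k, uc.value * lam, uc.unit, uc.price_year, uc.country)
                for k, uc in table.entries.items()
            },
            reference_year=table.reference_year,
        )
        rng = np.random.default_rng(13)
        rec = dataclasses.replace(
            random_record(rng, "H1"), other_medications_cost=0.0, other_medications_pe_cost=0.0
        )  # pass-through money is reported, not priced, so it does not scale
        bd = cost_patient(rec, table)
        bd_scaled = cost_patient(rec, scaled)
        for comp in COMPONENTS:
            assert bd_scaled.components[comp][0] == pytest.approx(
                lam * bd.components[comp][0], rel=1e-12
            )
            assert bd_scaled.components[comp][1] == pytest.approx(
                lam * bd.components[comp][1], rel=1e-12
            )

    def test_missing_price_propagates(self, fees):
        sparse = UnitCostTable(entries={})
        with pytest.raises(MissingPriceError):
            cost_patient(make_record(anticoagulation_days=1), sparse, fees)


def test_brute_force_oracle_equivalence(table, fees):
    """Engine output matches a naive item-by-item recomputation to 1e-9."""
    rng = np.random.default_rng(2024)
    for i in range(200):
        rec = random_record(rng, f"O{i}")
        bd = cost_patient(rec, table)
        oracle = brute_force_cost(rec, table, fees)
        for comp in COMPONENTS:
            assert bd.components[comp][0] == pytest.approx(oracle[comp][0], abs=1e-9)
            assert bd.components[comp][1] == pytest.approx(oracle[comp][1], abs=1e-9)
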