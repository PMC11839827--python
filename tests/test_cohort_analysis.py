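import numpy as np
import pytest

from conftest import make_record
from hrucost.cohort_analysis import (
    CIConfig,
    Classifier,
    SubgroupSpec,
    fractions_dict,
    has_comorbidity,
    is_fragile,
    round_half_up,
    stratify,
    summarise,
    table4_dataframe,
)
from hrucost.cost_engine import COMPONENTS, CostBreakdown, cost_cohort
from hrucost.hru_model import Comorbidity, Employment, Hospitalisation, ProductivityLossCategory, Sex

# Published component means (total, PE-attributable) used as a frozen input
# table to exercise the aggregation arithmetic.
PRINTED_MEANS = {
    "anticoagulation": (279.00, 279.00),
    "ambulatory_visits": (1873.04, 194.95),
    "rehospitalisation": (682.51, 296.83),
    "other_medications": (19.06, 3.46),
    "diagnostics": (44.98, 21.78),
    "other_medical": (33.90, 13.80),
    "formal_informal_help": (86.85, 52.82),
    "productivity_loss": (4010.29, 4010.29),
}


def _breakdown(pid, components):
    return CostBreakdown(patient_id=pid, components=dict(components))


def _flat_breakdown(pid, overall, attrib=None):
    comps = {c: (0.0, 0.0) for c in COMPONENTS}
    comps["anticoagulation"] = (overall, attrib if attrib is not None else 0.0)
    return _breakdown(pid, comps)


class TestSummarise:
    def test_two_patient_overall_mean(self):
        records = [make_record("P1"), make_record("P2")]
        bds = [_flat_breakdown("P1", 100.0), _flat_breakdown("P2", 300.0)]
        s = summarise(records, bds, compute_ci=False)
        assert s.overall_mean == pytest.approx(200.0)
        assert s.n == 2

    def test_fully_attributable_boundary(self):
        records = [make_record("P1"), make_record("P2")]
        bds = [_flat_breakdown("P1", 100.0, 100.0), _flat_breakdown("P2", 50.0, 50.0)]
        s = summarise(records, bds, compute_ci=False)
        assert s.attributable_fraction_overall == pytest.approx(1.0)

    def test_misaligned_inputs_error(self):
        records = [make_record("P1")]
        with pytest.raises(ValueError):
            summarise(records, [], compute_ci=False)
        with pytest.raises(ValueError):
            summarise(records, [_flat_breakdown("OTHER", 1.0)], compute_ci=False)

    def test_fraction_is_ratio_of_means_not_mean_of_ratios(self):
        # patient ratios are 1.0 and 0.0; ratio of means is 100/150
        records = [make_record("P1"), make_record("P2")]
        bds = [_flat_breakdown("P1", 100.0, 100.0), _flat_breakdown("P2", 50.0, 0.0)]
        s = summarise(records, bds, compute_ci=False)
        assert s.attributable_fraction_overall == pytest.approx(100.0 / 150.0)

    def test_printed_table_reproduces_published_fractions(self):
        records = [make_record("P1"), make_record("P2")]
        bds = [_breakdown(p, PRINTED_MEANS) for p in ("P1", "P2")]
        s = summarise(records, bds, compute_ci=False)
        assert s.overall_mean == pytest.approx(7029.63, abs=0.005)
        assert s.direct_attributable_mean == pytest.approx(862.64, abs=0.005)
        pct = fractions_dict(s)["percent_rendered"]
        assert pct["attributable_fraction_overall"] == "69.3"
        assert pct["attributable_fraction_direct"] == "28.6"
        assert pct["indirect_share_overall"] == "57.0"
        assert pct["indirect_share_attributable"] == "82.3"

    def test_empty_cohort_flagged_undefined(self):
        s = summarise([], [], compute_ci=False)
        assert s.undefined and s.n == 0 and s.overall_mean is None


class TestClassifiers:
    def test_comorbidity(self):
        assert has_comorbidity(make_record(comorbidities=frozenset({Comorbidity.DIABETES_MELLITUS})))
        assert not has_comorbidity(make_record())

    @pytest.mark.parametrize(
        "age,crcl,bmi,fragile",
        [
            (80, 70, 25, True),  # age criterion
            (75, 50, 18.5, False),  # all boundaries: strict inequalities
            (60, 45, 24, True),  # renal criterion
            (60, 90, 17.0, True),  # underweight criterion
            (60, 90, 24, False),
        ],
    )
    def test_fragility_strict_inequalities(self, age, crcl, bmi, fragile):
        rec = make_record(age=age, creatinine_clearance=crcl, bmi=bmi)
        assert is_fragile(rec) is fragile

    def test_fragility_missing_field_is_error(self):
        rec = make_record()
        rec.bmi = None
        with pytest.raises(ValueError):
            is_fragile(rec)


class TestStratify:
    def test_sex_partition(self, table):
        records = [
            make_record(f"P{i}", sex=Sex.FEMALE if i % 3 else Sex.MALE) for i in range(30)
        ]
        bds = cost_cohort(records, table)
        strata = stratify(records, bds, SubgroupSpec("sex", Classifier.SEX))
        assert strata["women"].n + strata["men"].n == 30

    def test_decomposition_identity(self, table):
        rng = np.random.default_rng(3)
        records = []
        for i in range(60):
            records.append(
                make_record(
                    f"P{i}",
                    age=float(rng.uniform(20, 90)),
                    anticoagulation_days=int(rng.integers(0, 91)),
                    employed_before_pe=Employment.YES if rng.random() < 0.5 else Employment.NO,
                    productivity_loss_category=list(ProductivityLossCategory)[int(rng.integers(3))],
                )
            )
        bds = cost_cohort(records, table)
        cohort_summary = summarise(records, bds, compute_ci=False)
        for classifier in Classifier:
            strata = stratify(records, bds, SubgroupSpec("s", classifier))
            total = sum(s.n * (s.overall_mean or 0.0) for s in strata.values())
            assert total == pytest.approx(60 * cohort_summary.overall_mean, rel=1e-12)

    def test_fragile_stay_fixture(self, table):
        """Fragile patients with one 10-day stay each: direct-mean gap is 10 x 658.27."""
        records, bds_in = [], []
        for i in range(20):
            fragile = i < 8
            rec = make_record(
                f"P{i}",
                age=80 if fragile else 50,
                hospitalisations=(Hospitalisation(10, True),) if fragile else (),
            )
            records.append(rec)
        bds = cost_cohort(records, table)
        strata = stratify(records, bds, SubgroupSpec("fragility", Classifier.FRAGILITY))
        gap = strata["fragile"].direct_mean - strata["non_fragile"].direct_mean
        assert gap == pytest.approx(10 * 658.27, rel=1e-12)

    def test_empty_stratum_not_nan(self, table):
        records = [make_record(f"P{i}", age=40) for i in range(5)]
        bds = cost_cohort(records, table)
        strata = stratify(records, bds, SubgroupSpec("age", Classifier.AGE_LE65_VS_GT65))
        assert strata["age_gt65"].undefined
        assert strata["age_gt65"].overall_mean is None
        assert strata["age_le65"].n == 5


class TestRendering:
    def test_round_half_up(self):
        assert round_half_up(7029.625, 2) == 7029.63
        assert round_half_up(0.285, 3) == 0.285
        assert round_half_up(28.55, 1) == 28.6

    def test_table4_structure_frozen_fixture(self, table):
        """Rendered component table is bit-stable for a frozen 2-patient cohort."""
        records = [make_record("P1"), make_record("P2")]
        bds = [_breakdown(p, PRINTED_MEANS) for p in ("P1", "P2")]
        s = summarise(records, bds, CIConfig(seed=0))
        df = table4_dataframe(s)
        assert list(df["component"])[:8] == list(COMPONENTS)
        text = df.to_csv(index=False)
        assert text == TABLE4_FROZEN


TABLE4_FROZEN = """\
component,label,costs_overall,sd_overall,costs_pe,sd_pe,ci_low,ci_high,ci_method
anticoagulation,Costs related to anticoagulation at follow-up,279.00,0.00,279.00,0.00,279.00,279.00,gamma_glm
ambulatory_visits,Costs related to ambulatory visits,1873.04,0.00,194.95,0.00,1873.04,1873.04,gamma_glm
rehospitalisation,Costs related to rehospitalisation,682.51,0.00,296.83,0.00,682.51,682.51,gamma_glm
other_medications,Costs related to medications other than anticoagulation,19.06,0.00,3.46,0.00,19.06,19.06,gamma_glm
diagnostics,Costs related to additional examinations,44.98,0.00,21.78,0.00,44.98,44.98,gamma_glm
other_medical,Costs related to other medical expenses,33.90,0.00,13.80,0.00,33.90,33.90,gamma_glm
formal_informal_help,Costs related to formal and informal help,86.85,0.00,52.82,0.00,86.85,86.85,gamma_glm
productivity_loss,Costs related to productivity loss,4010.29,0.00,4010.29,0.00,4010.29,4010.29,gamma_glm
direct_costs,Direct costs,3019.34,,862.64,,,,
indirect_costs,Indirect costs,4010.29,,4010.29,,,,
overall_costs,Overall costs,7029.63,,4872.93,,,,
"""
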