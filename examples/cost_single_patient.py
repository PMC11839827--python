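"""Cost one questionnaire record bottom-up.

Builds a typical post-PE follow-up questionnaire — 90 days of rivaroxaban,
a PE-related readmission, some visits and diagnostics, six weeks off work —
and prints the component-by-component cost breakdown: for each component the
total euros and the part the site investigator attributed to the PE.
"""

from hrucost import cost_patient, UnitCostTable
from hrucost.hru_model import (
    AmbulatoryGroup,
    Anticoagulant,
    CountWithPE,
    Employment,
    Hospitalisation,
    PatientRecord,
    ProductivityLossCategory,
    RehabEpisode,
    Sex,
    DIAGNOSTIC_MODALITIES,
    OTHER_ITEMS,
)

record = PatientRecord(
    patient_id="EX-001",
    age=58.0,
    sex=Sex.FEMALE,
    bmi=27.4,
    creatinine_clearance=88.0,
    employed_before_pe=Employment.YES,
    anticoagulant=Anticoagulant.RIVAROXABAN,
    anticoagulation_days=90,
    ambulatory_visits=(
        AmbulatoryGroup("general_practitioner", 6, 3),
        AmbulatoryGroup("specialist", 2, 1),
    ),
    hospitalisations=(Hospitalisation(length_of_stay=5, pe_related=True),),
    diagnostics={
        **{m: CountWithPE(0, 0) for m in DIAGNOSTIC_MODALITIES},
        "echocardiography": CountWithPE(1, 1),
        "compression_ultrasound": CountWithPE(1, 1),
    },
    rehab_inpatient=RehabEpisode(0),
    rehab_outpatient=RehabEpisode(0),
    help_visits=CountWithPE(0, 0),
    help_days=CountWithPE(0, 0),
    other_items={
        **{it: CountWithPE(0, 0) for it in OTHER_ITEMS},
        "compression_stockings": CountWithPE(1, 1),
    },
    other_medications_cost=0.0,
    other_medications_pe_cost=0.0,
    productivity_loss_category=ProductivityLossCategory.LE_6_WEEKS,
    answered_any_cost_question=True,
)

table = UnitCostTable.default()  # German 2021 unit costs
breakdown = cost_patient(record, table)

print(f"patient {breakdown.patient_id}")
for component, (total, pe) in breakdown.components.items():
    print(f"  {component:22s} {total:9.2f} EUR   PE-attributable {pe:9.2f} EUR")
print(f"  {'direct total':22s} {breakdown.direct_total:9.2f} EUR")
print(f"  {'indirect total':22s} {breakdown.indirect_total:9.2f} EUR")
print(f"  {'overall':22s} {breakdown.overall_total:9.2f} EUR "
      f"({breakdown.pe_attributable_total:.2f} EUR attributed to the PE)")
# The productivity row is 21 days x 343.95 EUR: the categorical "<= 6 weeks"
# answer is imputed as 3 weeks of absence, valued by the human-capital method.
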