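"""Independent brute-force recomputation of per-patient costs.

Deliberately naive: walks every resource item of a record one unit at a time
and accumulates euros from the price registry, with no shared code with the
cost engine beyond price lookup. Used as the equivalence oracle.
"""

from hrucost.hru_model import Employment, PatientRecord, ProductivityLossCategory
from hrucost.unit_costs import UnitCostTable

_DRUG = {
    "rivaroxaban": "rivaroxaban_day",
    "enoxaparin": "enoxaparin_day",
    "tinzaparin": "tinzaparin_day",
    "fondaparinux": "fondaparinux_day",
}


def brute_force_cost(
    record: PatientRecord,
    table: UnitCostTable,
    fees: dict[str, float],
    le6_days: int = 21,
    gt6_days: int = 63,
) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}

    drug_price = table.lookup(_DRUG[record.anticoagulant.value]).value
    t = 0.0
    for _ in range(record.anticoagulation_days or 0):
        t += drug_price
    out["anticoagulation"] = (t, t)

    t = a = 0.0
    for g in record.ambulatory_visits or ():
        for _ in range(g.count):
            t += fees[g.specialty]
        for _ in range(g.pe_related_count):
            a += fees[g.specialty]
    out["ambulatory_visits"] = (t, a)

    day = table.lookup("hospital_day").value
    t = a = 0.0
    for h in record.hospitalisations or ():
        t += h.length_of_stay * day
        if h.pe_related:
            a += h.length_of_stay * day
    out["rehospitalisation"] = (t, a)

    out["other_medications"] = (
        record.other_medications_cost or 0.0,
        record.other_medications_pe_cost or 0.0,
    )

    t = a = 0.0
    for modality, d in (record.diagnostics or {}).items():
        price = table.lookup(modality).value
        for _ in range(d.count):
            t += price
        for _ in range(d.pe_related_count):
            a += price
    out["diagnostics"] = (t, a)

    t = a = 0.0
    for item, c in (record.other_items or {}).items():
        price = table.lookup(item).value
        for _ in range(c.count):
            t += price
        for _ in range(c.pe_related_count):
            a += price
    out["other_medical"] = (t, a)

    visit = table.lookup("help_visit").value
    rehab = table.lookup("rehab_day").value
    hv = record.help_visits
    t = (hv.count if hv else 0) * visit
    a = (hv.pe_related_count if hv else 0) * visit
    for ep in (record.rehab_inpatient, record.rehab_outpatient):
        if ep is None:
            continue
        t += ep.days * rehab
        if ep.pe_related:
            a += ep.days * rehab
    out["formal_informal_help"] = (t, a)

    if record.employed_before_pe is Employment.YES:
        cat = record.productivity_loss_category or ProductivityLossCategory.NONE
        days = {"none": 0, "le_6_weeks": le6_days, "gt_6_weeks": gt6_days}[cat.value]
    else:
        days = 0
    t = days * table.lookup("productivity_day").value
    out["productivity_loss"] = (t, t)
    return out
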