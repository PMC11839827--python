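"""Bottom-up per-patient costing.

Each resource-use field of a questionnaire record is multiplied by its
registered unit cost, separately for the total and for the PE-attributed
sub-counts, and assembled into a :class:`CostBreakdown` with eight
components: seven direct (anticoagulation, ambulatory visits,
rehospitalisation, non-anticoagulant medications, diagnostics, other medical
expenses, formal/informal help incl. rehabilitation) and one indirect
(productivity loss). All arithmetic is at full floating precision; no
rounding happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .hru_model import (
    AmbulatoryGroup,
    Anticoagulant,
    CountWithPE,
    Hospitalisation,
    PatientRecord,
)
from .productivity import AbsenceImputation, productivity_cost
from .unit_costs import AMBULATORY_FEE_PREFIX, MissingPriceError, UnitCostTable

__all__ = [
    "COMPONENTS",
    "DIRECT_COMPONENTS",
    "CostBreakdown",
    "anticoagulation_cost",
    "hospitalisation_cost",
    "ambulatory_cost",
    "diagnostics_cost",
    "help_and_rehab_cost",
    "other_medical_cost",
    "cost_patient",
    "cost_cohort",
]

DIRECT_COMPONENTS = (
    "anticoagulation",
    "ambulatory_visits",
    "rehospitalisation",
    "other_medications",
    "diagnostics",
    "other_medical",
    "formal_informal_help",
)
COMPONENTS = DIRECT_COMPONENTS + ("productivity_loss",)

_DRUG_ITEM = {
    Anticoagulant.RIVAROXABAN: "rivaroxaban_day",
    Anticoagulant.ENOXAPARIN: "enoxaparin_day",
    Anticoagulant.TINZAPARIN: "tinzaparin_day",
    Anticoagulant.FONDAPARINUX: "fondaparinux_day",
}


@dataclass
class CostBreakdown:
    """Per-patient component costs, each as (total €, PE-attributable €)."""

    patient_id: str
    components: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def direct_total(self) -> float:
        return sum(self.components[c][0] for c in DIRECT_COMPONENTS)

    @property
    def direct_attributable(self) -> float:
        return sum(self.components[c][1] for c in DIRECT_COMPONENTS)

    @property
    def indirect_total(self) -> float:
        return self.components["productivity_loss"][0]

    @property
    def indirect_attributable(self) -> float:
        return self.components["productivity_loss"][1]

    @property
    def overall_total(self) -> float:
        return self.direct_total + self.indirect_total

    @property
    def pe_attributable_total(self) -> float:
        return self.direct_attributable + self.indirect_attributable

    def validate(self) -> None:
        for name in COMPONENTS:
            if name not in self.components:
                raise ValueError(f"missing component {name!r}")
            total, attrib = self.components[name]
            if not (0 <= attrib <= total + 1e-9):
                raise ValueError(
                    f"component {name!r}: attributable {attrib} outside [0, total={total}]"
                )


def anticoagulation_cost(
    drug: Anticoagulant, days: int, table: UnitCostTable
) -> tuple[float, float]:
    """Drug-days x per-day price; fully PE-attributable (index-event therapy)."""
    if days < 0:
        raise ValueError(f"anticoagulation days must be >= 0, got {days}")
    total = days * table.price(_DRUG_ITEM[Anticoagulant(drug)])
    return (total, total)


def hospitalisation_cost(
    stays: Iterable[Hospitalisation] | Sequence[tuple[float, bool]],
    table: UnitCostTable,
) -> tuple[float, float]:
    """Inpatient days x per-day price; attributable part sums PE-related stays."""
    price = table.price("hospital_day")
    total = 0.0
    attrib = 0.0
    for stay in stays:
        if isinstance(stay, Hospitalisation):
            los, pe = stay.length_of_stay, stay.pe_related
        else:
            los, pe = stay
        if los < 0:
            raise ValueError(f"length of stay must be >= 0, got {los}")
        cost = los * price
        total += cost
        if pe:
            attrib += cost
    return (total, attrib)


def ambulatory_cost(
    visits: Iterable[AmbulatoryGroup] | Sequence[tuple[str, int, int]],
    fees: Mapping[str, float],
) -> tuple[float, float]:
    """Visit counts x per-specialty fee (statutory-insurance fee map)."""
    total = 0.0
    attrib = 0.0
    for g in visits:
        if isinstance(g, AmbulatoryGroup):
            specialty, count, pe_count = g.specialty, g.count, g.pe_related_count
        else:
            specialty, count, pe_count = g
        if specialty not in fees:
            raise MissingPriceError(AMBULATORY_FEE_PREFIX + specialty)
        fee = fees[specialty]
        total += count * fee
        attrib += pe_count * fee
    return (total, attrib)


def diagnostics_cost(
    diagnostics: Mapping[str, CountWithPE | tuple[int, int]],
    table: UnitCostTable,
) -> tuple[float, float]:
    """Examination counts x per-examination price, per modality."""
    total = 0.0
    attrib = 0.0
    for modality, d in diagnostics.items():
        count, pe_count = (d.count, d.pe_related_count) if isinstance(d, CountWithPE) else d
        price = table.price(modality)
        total += count * price
        attrib += pe_count * price
    return (total, attrib)


def help_and_rehab_cost(record: PatientRecord, table: UnitCostTable) -> tuple[float, float]:
    """Formal/informal help visits plus rehabilitation days.

    Help is priced per visit from the visit count (the ``help_days`` field is
    descriptive only); rehabilitation days (either setting) are priced per
    clinic day.
    """
    help_price = table.price("help_visit")
    rehab_price = table.price("rehab_day")
    hv = record.help_visits or CountWithPE(0, 0)
    total = hv.count * help_price
    attrib = hv.pe_related_count * help_price
    for ep in (record.rehab_inpatient, record.rehab_outpatient):
        if ep is None:
            continue
        cost = ep.days * rehab_price
        total += cost
        if ep.pe_related:
            attrib += cost
    return (total, attrib)


def other_medical_cost(
    other_items: Mapping[str, CountWithPE | tuple[int, int]],
    table: UnitCostTable,
) -> tuple[float, float]:
    """Sundry medical items (physiotherapy, stockings, breathing training)."""
    total = 0.0
    attrib = 0.0
    for item, c in other_items.items():
        count, pe_count = (c.count, c.pe_related_count) if isinstance(c, CountWithPE) else c
        price = table.price(item)
        total += count * price
        attrib += pe_count * price
    return (total, attrib)


def cost_patient(
    record: PatientRecord,
    table: UnitCostTable,
    fees: Mapping[str, float] | None = None,
    imputation: AbsenceImputation = AbsenceImputation(),
) -> CostBreakdown:
    """Assemble the full per-patient cost breakdown.

    ``fees`` defaults to the per-specialty ambulatory fee map registered in
    the unit-cost table. The record must already have passed the missing
    policy (no ``None`` cost fields).
    """
    if fees is None:
        fees = table.fee_schedule()
    bd = CostBreakdown(patient_id=record.patient_id)
    bd.components["anticoagulation"] = anticoagulation_cost(
        record.anticoagulant, record.anticoagulation_days or 0, table
    )
    bd.components["ambulatory_visits"] = ambulatory_cost(record.ambulatory_visits or (), fees)
    bd.components["rehospitalisation"] = hospitalisation_cost(record.hospitalisations or (), table)
    med_total = record.other_medications_cost or 0.0
    med_pe = record.other_medications_pe_cost or 0.0
    bd.components["other_medications"] = (med_total, med_pe)
    bd.components["diagnostics"] = diagnostics_cost(record.diagnostics or {}, table)
    bd.components["other_medical"] = other_medical_cost(record.other_items or {}, table)
    bd.components["formal_informal_help"] = help_and_rehab_cost(record, table)
    bd.components["productivity_loss"] = productivity_cost(record, table, imputation)
    bd.validate()
    return bd


def cost_cohort(
    records: Iterable[PatientRecord],
    table: UnitCostTable,
    fees: Mapping[str, float] | None = None,
    imputation: AbsenceImputation = AbsenceImputation(),
) -> list[CostBreakdown]:
    """Cost every record of a cohort (order-preserving)."""
    return [cost_patient(r, table, fees, imputation) for r in records]
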