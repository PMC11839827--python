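import numpy as np
import pytest

from hrucost.hru_model import (
    AmbulatoryGroup,
    Anticoagulant,
    Comorbidity,
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
from hrucost.unit_costs import UnitCostTable


@pytest.fixture(scope="session")
def table() -> UnitCostTable:
    return UnitCostTable.default()


@pytest.fixture(scope="session")
def fees(table) -> dict[str, float]:
    return table.fee_schedule()


def make_record(patient_id="P1", **overrides) -> PatientRecord:
    """A fully answered, all-zero-utilisation record; override per test."""
    base = dict(
        patient_id=patient_id,
        age=55.0,
        sex=Sex.MALE,
        bmi=26.0,
        creatinine_clearance=85.0,
        employed_before_pe=Employment.NO,
        comorbidities=frozenset(),
        anticoagulant=Anticoagulant.RIVAROXABAN,
        anticoagulation_days=0,
        ambulatory_visits=(),
        hospitalisations=(),
        diagnostics={m: CountWithPE(0, 0) for m in DIAGNOSTIC_MODALITIES},
        rehab_inpatient=RehabEpisode(0, False),
        rehab_outpatient=RehabEpisode(0, False),
        help_visits=CountWithPE(0, 0),
        help_days=CountWithPE(0, 0),
        other_items={it: CountWithPE(0, 0) for it in OTHER_ITEMS},
        other_medications_cost=0.0,
        other_medications_pe_cost=0.0,
        productivity_loss_category=ProductivityLossCategory.NONE,
        answered_any_cost_question=True,
    )
    base.update(overrides)
    return PatientRecord(**base)


def random_record(rng: np.random.Generator, patient_id: str) -> PatientRecord:
    """A small random (but valid) record for oracle-equivalence checks."""

    def pick(enum_cls):
        members = list(enum_cls)
        return members[int(rng.integers(len(members)))]

    def cwp(hi):
        c = int(rng.integers(0, hi))
        return CountWithPE(c, int(rng.integers(0, c + 1)))

    med = float(rng.uniform(0, 80)) if rng.random() < 0.4 else 0.0
    stays = tuple(
        Hospitalisation(int(rng.integers(1, 15)), bool(rng.random() < 0.5))
        for _ in range(int(rng.integers(0, 3)))
    )
    visits = []
    for specialty in ("general_practitioner", "specialist"):
        if rng.random() < 0.7:
            c = int(rng.integers(0, 12))
            visits.append(AmbulatoryGroup(specialty, c, int(rng.integers(0, c + 1))))
    return make_record(
        patient_id=patient_id,
        age=float(rng.uniform(19, 95)),
        sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
        bmi=float(rng.uniform(16, 45)),
        creatinine_clearance=float(rng.uniform(20, 130)),
        employed_before_pe=pick(Employment),
        comorbidities=frozenset(c for c in Comorbidity if rng.random() < 0.15),
        anticoagulant=pick(Anticoagulant),
        anticoagulation_days=int(rng.integers(0, 91)),
        ambulatory_visits=tuple(visits),
        hospitalisations=stays,
        diagnostics={m: cwp(3) for m in DIAGNOSTIC_MODALITIES},
        rehab_inpatient=RehabEpisode(int(rng.integers(0, 40)), bool(rng.random() < 0.5)),
        rehab_outpatient=RehabEpisode(int(rng.integers(0, 40)), bool(rng.random() < 0.5)),
        help_visits=cwp(20),
        other_items={it: cwp(4) for it in OTHER_ITEMS},
        other_medications_cost=med,
        other_medications_pe_cost=float(rng.uniform(0, med)) if med else 0.0,
        productivity_loss_category=pick(ProductivityLossCategory),
    )
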