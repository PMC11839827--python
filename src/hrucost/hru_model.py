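"""Patient questionnaire data model, CSV I/O, validation and missing-data policy.

One record per patient captures everything the 3-month follow-up healthcare
resource utilisation (HRU) questionnaire asks after an acute low-risk
pulmonary embolism: demographics, the five tracked comorbidities,
anticoagulation, ambulatory physician visits by specialty, rehospitalisations,
follow-up diagnostics, rehabilitation, formal/informal help, sundry medical
items, self-reported non-anticoagulant medication spending, and the
categorical work-absence answer. Every countable resource carries a
disease-attribution sub-count (``pe_related``) filled in by the site
investigator, which drives the excess-cost (PE-attributable) analysis.

Missing-data policy: missing answers in a cost category mean *no utilisation*
and are replaced with zero, provided the patient answered at least one cost
question; patients who answered none are excluded from the cohort denominator.

CSV dialect (schema version ``1``): UTF-8, comma-separated, mandatory header;
repeated groups are flattened as ``amb_<k>_*`` (ambulatory specialty groups,
k = 1..4) and ``hosp_<k>_*`` (hospital stays, k = 1..5); missing is the empty
string; booleans are ``1``/``0``.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

__all__ = [
    "Sex",
    "Employment",
    "Anticoagulant",
    "ProductivityLossCategory",
    "Comorbidity",
    "AmbulatoryGroup",
    "Hospitalisation",
    "CountWithPE",
    "RehabEpisode",
    "PatientRecord",
    "Cohort",
    "ValidationIssue",
    "RecordValidationError",
    "SchemaError",
    "apply_missing_policy",
    "read_cohort",
    "write_cohort",
    "csv_columns",
    "DIAGNOSTIC_MODALITIES",
    "OTHER_ITEMS",
    "MAX_AMBULATORY_GROUPS",
    "MAX_HOSPITALISATIONS",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"
MAX_AMBULATORY_GROUPS = 4
MAX_HOSPITALISATIONS = 5

DIAGNOSTIC_MODALITIES = (
    "chest_xray",
    "ct",
    "mrt",
    "endoscopy_bronchoscopy",
    "lung_scintigraphy",
    "echocardiography",
    "compression_ultrasound",
)

OTHER_ITEMS = ("physiotherapy", "compression_stockings", "breathing_training")


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Employment(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Anticoagulant(str, enum.Enum):
    RIVAROXABAN = "rivaroxaban"
    ENOXAPARIN = "enoxaparin"
    TINZAPARIN = "tinzaparin"
    FONDAPARINUX = "fondaparinux"


class ProductivityLossCategory(str, enum.Enum):
    """Work-absence duration as the questionnaire dichotomises it."""

    NONE = "none"
    LE_6_WEEKS = "le_6_weeks"
    GT_6_WEEKS = "gt_6_weeks"


class Comorbidity(str, enum.Enum):
    ACTIVE_CANCER = "active_cancer"
    COPD = "copd"
    CHRONIC_HEART_FAILURE = "chronic_heart_failure"
    CORONARY_ARTERY_DISEASE = "coronary_artery_disease"
    DIABETES_MELLITUS = "diabetes_mellitus"


@dataclass(frozen=True)
class AmbulatoryGroup:
    """Visits to one physician specialty: total and PE-attributed counts."""

    specialty: str
    count: int
    pe_related_count: int = 0


@dataclass(frozen=True)
class Hospitalisation:
    """One follow-up inpatient stay."""

    length_of_stay: int  # days
    pe_related: bool = False


@dataclass(frozen=True)
class CountWithPE:
    """A resource count with its PE-attributed sub-count."""

    count: int
    pe_related_count: int = 0


@dataclass(frozen=True)
class RehabEpisode:
    """Rehabilitation days in one setting, flagged PE-related or not."""

    days: int
    pe_related: bool = False


class RecordValidationError(ValueError):
    """A patient record violates the questionnaire invariants."""

    def __init__(self, issues: list[str]):
        super().__init__("; ".join(issues))
        self.issues = issues


class SchemaError(ValueError):
    """The CSV file does not conform to the documented schema."""


class ValidationIssue(NamedTuple):
    row: int  # 1-based data row number
    patient_id: str
    fieldname: str
    issue: str


@dataclass
class PatientRecord:
    """One HRU questionnaire, possibly with missing (``None``) cost fields.

    ``None`` in a cost field means the question was unanswered; the
    missing-data policy (:func:`apply_missing_policy`) resolves them before
    costing. Demographics are mandatory.
    """

    patient_id: str
    age: float
    sex: Sex
    bmi: float
    creatinine_clearance: float
    employed_before_pe: Employment
    comorbidities: frozenset[Comorbidity] = frozenset()
    anticoagulant: Anticoagulant = Anticoagulant.RIVAROXABAN
    anticoagulation_days: Optional[int] = None
    ambulatory_visits: Optional[tuple[AmbulatoryGroup, ...]] = None
    hospitalisations: Optional[tuple[Hospitalisation, ...]] = None
    diagnostics: Optional[dict[str, CountWithPE]] = None
    rehab_inpatient: Optional[RehabEpisode] = None
    rehab_outpatient: Optional[RehabEpisode] = None
    help_visits: Optional[CountWithPE] = None
    help_days: Optional[CountWithPE] = None  # descriptive; costing uses visits
    other_items: Optional[dict[str, CountWithPE]] = None
    other_medications_cost: Optional[float] = None
    other_medications_pe_cost: Optional[float] = None
    productivity_loss_category: Optional[ProductivityLossCategory] = None
    answered_any_cost_question: bool = False

    # Cost-question fields in questionnaire order; the missing policy and the
    # answered_any flag are defined over exactly this set.
    _COST_FIELDS = (
        "anticoagulation_days",
        "ambulatory_visits",
        "hospitalisations",
        "diagnostics",
        "rehab_inpatient",
        "rehab_outpatient",
        "help_visits",
        "help_days",
        "other_items",
        "other_medications_cost",
        "other_medications_pe_cost",
        "productivity_loss_category",
    )

    def any_cost_answer(self) -> bool:
        return any(getattr(self, f) is not None for f in self._COST_FIELDS)

    def validate(self) -> None:
        """Raise :class:`RecordValidationError` on any invariant violation."""
        issues: list[str] = []

        def chk(ok: bool, msg: str) -> None:
            if not ok:
                issues.append(msg)

        chk(bool(self.patient_id), "patient_id: empty")
        chk(19 <= self.age <= 120, f"age: {self.age} outside accepted range [19, 120]")
        chk(self.bmi > 0, f"bmi: {self.bmi} must be positive")
        chk(
            self.creatinine_clearance > 0,
            f"creatinine_clearance: {self.creatinine_clearance} must be positive",
        )
        if self.anticoagulation_days is not None:
            chk(self.anticoagulation_days >= 0, "anticoagulation_days: negative")
        for g in self.ambulatory_visits or ():
            chk(g.count >= 0, f"ambulatory_visits[{g.specialty}]: negative count")
            chk(
                0 <= g.pe_related_count <= g.count,
                f"ambulatory_visits[{g.specialty}]: pe_related_count {g.pe_related_count} "
                f"exceeds count {g.count}",
            )
        for i, h in enumerate(self.hospitalisations or ()):
            chk(h.length_of_stay >= 0, f"hospitalisations[{i}]: negative length_of_stay")
        for modality, d in (self.diagnostics or {}).items():
            chk(modality in DIAGNOSTIC_MODALITIES, f"diagnostics: unknown modality {modality!r}")
            chk(d.count >= 0, f"diagnostics[{modality}]: negative count")
            chk(
                0 <= d.pe_related_count <= d.count,
                f"diagnostics[{modality}]: pe_related_count {d.pe_related_count} "
                f"exceeds count {d.count}",
            )
        for setting, ep in (("inpatient", self.rehab_inpatient), ("outpatient", self.rehab_outpatient)):
            if ep is not None:
                chk(ep.days >= 0, f"rehab_{setting}: negative days")
        for name, c in (("help_visits", self.help_visits), ("help_days", self.help_days)):
            if c is not None:
                chk(c.count >= 0, f"{name}: negative count")
                chk(
                    0 <= c.pe_related_count <= c.count,
                    f"{name}: pe_related_count {c.pe_related_count} exceeds count {c.count}",
                )
        for item, c in (self.other_items or {}).items():
            chk(item in OTHER_ITEMS, f"other_items: unknown item {item!r}")
            chk(c.count >= 0, f"other_items[{item}]: negative count")
            chk(
                0 <= c.pe_related_count <= c.count,
                f"other_items[{item}]: pe_related_count {c.pe_related_count} exceeds count {c.count}",
            )
        if self.other_medications_cost is not None:
            chk(self.other_medications_cost >= 0, "other_medications_cost: negative")
            pe = self.other_medications_pe_cost or 0.0
            chk(
                0 <= pe <= self.other_medications_cost + 1e-9,
                f"other_medications_pe_cost: {pe} exceeds total {self.other_medications_cost}",
            )
        if issues:
            raise RecordValidationError(issues)


def apply_missing_policy(record: PatientRecord) -> Optional[PatientRecord]:
    """Resolve missing cost answers: zero-fill if anything was answered.

    Returns the zero-filled record (with ``answered_any_cost_question`` set)
    if at least one cost question was answered, else ``None`` — the patient is
    excluded from the cohort denominator. Idempotent.
    """
    if not record.any_cost_answer():
        return None
    empty_dx = {m: CountWithPE(0, 0) for m in DIAGNOSTIC_MODALITIES}
    empty_items = {it: CountWithPE(0, 0) for it in OTHER_ITEMS}
    filled = replace(
        record,
        anticoagulation_days=record.anticoagulation_days or 0,
        ambulatory_visits=record.ambulatory_visits if record.ambulatory_visits is not None else (),
        hospitalisations=record.hospitalisations if record.hospitalisations is not None else (),
        diagnostics={**empty_dx, **(record.diagnostics or {})},
        rehab_inpatient=record.rehab_inpatient or RehabEpisode(0, False),
        rehab_outpatient=record.rehab_outpatient or RehabEpisode(0, False),
        help_visits=record.help_visits or CountWithPE(0, 0),
        help_days=record.help_days or CountWithPE(0, 0),
        other_items={**empty_items, **(record.other_items or {})},
        other_medications_cost=record.other_medications_cost or 0.0,
        other_medications_pe_cost=record.other_medications_pe_cost or 0.0,
        productivity_loss_category=record.productivity_loss_category
        or ProductivityLossCategory.NONE,
        answered_any_cost_question=True,
    )
    return filled


@dataclass
class Cohort:
    """Included patient records plus the validation report of a read."""

    records: list[PatientRecord] = field(default_factory=list)
    validation_report: list[ValidationIssue] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# --------------------------------------------------------------------- CSV


def csv_columns() -> list[str]:
    """The schema-1 column list, in canonical order."""
    cols = [
        "patient_id",
        "age",
        "sex",
        "bmi",
        "creatinine_clearance",
        "employed_before_pe",
    ]
    cols += [f"com_{c.value}" for c in Comorbidity]
    cols += ["anticoagulant", "anticoagulation_days"]
    for k in range(1, MAX_AMBULATORY_GROUPS + 1):
        cols += [f"amb_{k}_specialty", f"amb_{k}_count", f"amb_{k}_pe_count"]
    for k in range(1, MAX_HOSPITALISATIONS + 1):
        cols += [f"hosp_{k}_los", f"hosp_{k}_pe"]
    for m in DIAGNOSTIC_MODALITIES:
        cols += [f"dx_{m}_count", f"dx_{m}_pe_count"]
    cols += [
        "rehab_inpatient_days",
        "rehab_inpatient_pe",
        "rehab_outpatient_days",
        "rehab_outpatient_pe",
        "help_visits",
        "help_visits_pe_count",
        "help_days",
        "help_days_pe_count",
    ]
    for it in OTHER_ITEMS:
        cols += [f"other_{it}_count", f"other_{it}_pe_count"]
    cols += [
        "other_medications_cost",
        "other_medications_pe_cost",
        "productivity_loss_category",
    ]
    return cols


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, enum.Enum):
        return v.value
    if isinstance(v, float):
        return repr(v)  # shortest round-trippable representation
    return str(v)


def _record_to_row(r: PatientRecord) -> dict[str, str]:
    row: dict[str, str] = {c: "" for c in csv_columns()}
    row["patient_id"] = r.patient_id
    row["age"] = _fmt(r.age)
    row["sex"] = r.sex.value
    row["bmi"] = _fmt(r.bmi)
    row["creatinine_clearance"] = _fmt(r.creatinine_clearance)
    row["employed_before_pe"] = r.employed_before_pe.value
    for c in Comorbidity:
        row[f"com_{c.value}"] = "1" if c in r.comorbidities else "0"
    row["anticoagulant"] = r.anticoagulant.value
    row["anticoagulation_days"] = _fmt(r.anticoagulation_days)
    for k, g in enumerate(r.ambulatory_visits or (), start=1):
        if k > MAX_AMBULATORY_GROUPS:
            raise SchemaError(
                f"patient {r.patient_id}: more than {MAX_AMBULATORY_GROUPS} ambulatory groups"
            )
        row[f"amb_{k}_specialty"] = g.specialty
        row[f"amb_{k}_count"] = _fmt(g.count)
        row[f"amb_{k}_pe_count"] = _fmt(g.pe_related_count)
    for k, h in enumerate(r.hospitalisations or (), start=1):
        if k > MAX_HOSPITALISATIONS:
            raise SchemaError(
                f"patient {r.patient_id}: more than {MAX_HOSPITALISATIONS} hospitalisations"
            )
        row[f"hosp_{k}_los"] = _fmt(h.length_of_stay)
        row[f"hosp_{k}_pe"] = _fmt(h.pe_related)
    for m in DIAGNOSTIC_MODALITIES:
        d = (r.diagnostics or {}).get(m)
        if d is not None:
            row[f"dx_{m}_count"] = _fmt(d.count)
            row[f"dx_{m}_pe_count"] = _fmt(d.pe_related_count)
    if r.rehab_inpatient is not None:
        row["rehab_inpatient_days"] = _fmt(r.rehab_inpatient.days)
        row["rehab_inpatient_pe"] = _fmt(r.rehab_inpatient.pe_related)
    if r.rehab_outpatient is not None:
        row["rehab_outpatient_days"] = _fmt(r.rehab_outpatient.days)
        row["rehab_outpatient_pe"] = _fmt(r.rehab_outpatient.pe_related)
    if r.help_visits is not None:
        row["help_visits"] = _fmt(r.help_visits.count)
        row["help_visits_pe_count"] = _fmt(r.help_visits.pe_related_count)
    if r.help_days is not None:
        row["help_days"] = _fmt(r.help_days.count)
        row["help_days_pe_count"] = _fmt(r.help_days.pe_related_count)
    for it in OTHER_ITEMS:
        c = (r.other_items or {}).get(it)
        if c is not None:
            row[f"other_{it}_count"] = _fmt(c.count)
            row[f"other_{it}_pe_count"] = _fmt(c.pe_related_count)
    row["other_medications_cost"] = _fmt(r.other_medications_cost)
    row["other_medications_pe_cost"] = _fmt(r.other_medications_pe_cost)
    if r.productivity_loss_category is not None:
        row["productivity_loss_category"] = r.productivity_loss_category.value
    return row


def write_cohort(records: Iterable[PatientRecord] | Cohort, path: str | Path) -> None:
    """Write records to a schema-1 CSV (lossless round-trip with read_cohort)."""
    if isinstance(records, Cohort):
        records = records.records
    cols = csv_columns()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols, lineterminator="\n")
        w.writeheader()
        for r in records:
            w.writerow(_record_to_row(r))


class _FieldError(Exception):
    def __init__(self, fieldname: str, issue: str):
        self.fieldname = fieldname
        self.issue = issue


def _parse_int(raw: str, fieldname: str) -> Optional[int]:
    if raw == "":
        return None
    try:
        f = float(raw)
    except ValueError:
        raise _FieldError(fieldname, f"not a number: {raw!r}") from None
    if f != int(f):
        raise _FieldError(fieldname, f"fractional value not allowed: {raw!r}")
    return int(f)


def _parse_float(raw: str, fieldname: str) -> Optional[float]:
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise _FieldError(fieldname, f"not a number: {raw!r}") from None


def _parse_bool(raw: str, fieldname: str) -> Optional[bool]:
    if raw == "":
        return None
    low = raw.strip().lower()
    if low in ("1", "true", "yes"):
        return True
    if low in ("0", "false", "no"):
        return False
    raise _FieldError(fieldname, f"not a boolean: {raw!r}")


def _parse_enum(raw: str, cls, fieldname: str):
    if raw == "":
        return None
    try:
        return cls(raw.strip().lower())
    except ValueError:
        allowed = "/".join(e.value for e in cls)
        raise _FieldError(fieldname, f"invalid value {raw!r}, expected one of {allowed}") from None


def _require(value, fieldname: str):
    if value is None:
        raise _FieldError(fieldname, "required field is missing")
    return value


def _row_to_record(row: dict[str, str]) -> PatientRecord:
    pid = row.get("patient_id", "").strip()
    if not pid:
        raise _FieldError("patient_id", "required field is missing")

    def count_pair(count_col: str, pe_col: str) -> Optional[CountWithPE]:
        c = _parse_int(row[count_col], count_col)
        pe = _parse_int(row[pe_col], pe_col)
        if c is None and pe is None:
            return None
        return CountWithPE(c or 0, pe or 0)

    amb: list[AmbulatoryGroup] = []
    amb_any = False
    for k in range(1, MAX_AMBULATORY_GROUPS + 1):
        spec = row[f"amb_{k}_specialty"].strip()
        c = _parse_int(row[f"amb_{k}_count"], f"amb_{k}_count")
        pe = _parse_int(row[f"amb_{k}_pe_count"], f"amb_{k}_pe_count")
        if spec == "" and c is None and pe is None:
            continue
        amb_any = True
        if spec == "":
            raise _FieldError(f"amb_{k}_specialty", "specialty missing for a visit group")
        amb.append(AmbulatoryGroup(spec, c or 0, pe or 0))

    hosp: list[Hospitalisation] = []
    hosp_any = False
    for k in range(1, MAX_HOSPITALISATIONS + 1):
        los = _parse_int(row[f"hosp_{k}_los"], f"hosp_{k}_los")
        pe = _parse_bool(row[f"hosp_{k}_pe"], f"hosp_{k}_pe")
        if los is None and pe is None:
            continue
        hosp_any = True
        hosp.append(Hospitalisation(_require(los, f"hosp_{k}_los"), bool(pe)))

    dx: dict[str, CountWithPE] = {}
    for m in DIAGNOSTIC_MODALITIES:
        pair = count_pair(f"dx_{m}_count", f"dx_{m}_pe_count")
        if pair is not None:
            dx[m] = pair

    items: dict[str, CountWithPE] = {}
    for it in OTHER_ITEMS:
        pair = count_pair(f"other_{it}_count", f"other_{it}_pe_count")
        if pair is not None:
            items[it] = pair

    def rehab(setting: str) -> Optional[RehabEpisode]:
        days = _parse_int(row[f"rehab_{setting}_days"], f"rehab_{setting}_days")
        pe = _parse_bool(row[f"rehab_{setting}_pe"], f"rehab_{setting}_pe")
        if days is None and pe is None:
            return None
        return RehabEpisode(days or 0, bool(pe))

    comorbidities = frozenset(
        c for c in Comorbidity if _parse_bool(row[f"com_{c.value}"], f"com_{c.value}")
    )

    rec = PatientRecord(
        patient_id=pid,
        age=_require(_parse_float(row["age"], "age"), "age"),
        sex=_require(_parse_enum(row["sex"], Sex, "sex"), "sex"),
        bmi=_require(_parse_float(row["bmi"], "bmi"), "bmi"),
        creatinine_clearance=_require(
            _parse_float(row["creatinine_clearance"], "creatinine_clearance"),
            "creatinine_clearance",
        ),
        employed_before_pe=_require(
            _parse_enum(row["employed_before_pe"], Employment, "employed_before_pe"),
            "employed_before_pe",
        ),
        comorbidities=comorbidities,
        anticoagulant=_parse_enum(row["anticoagulant"], Anticoagulant, "anticoagulant")
        or Anticoagulant.RIVAROXABAN,
        anticoagulation_days=_parse_int(row["anticoagulation_days"], "anticoagulation_days"),
        ambulatory_visits=tuple(amb) if amb_any else None,
        hospitalisations=tuple(hosp) if hosp_any else None,
        diagnostics=dx or None,
        rehab_inpatient=rehab("inpatient"),
        rehab_outpatient=rehab("outpatient"),
        help_visits=count_pair("help_visits", "help_visits_pe_count"),
        help_days=count_pair("help_days", "help_days_pe_count"),
        other_items=items or None,
        other_medications_cost=_parse_float(row["other_medications_cost"], "other_medications_cost"),
        other_medications_pe_cost=_parse_float(
            row["other_medications_pe_cost"], "other_medications_pe_cost"
        ),
        productivity_loss_category=_parse_enum(
            row["productivity_loss_category"], ProductivityLossCategory, "productivity_loss_category"
        ),
    )
    return rec


def read_cohort(path: str | Path, schema_version: str = SCHEMA_VERSION) -> Cohort:
    """Read and validate a schema-1 cohort CSV, applying the missing policy.

    Rows violating the schema or record invariants are rejected and reported
    in ``Cohort.validation_report``; rows with every cost question blank are
    excluded (policy, also reported). The returned cohort contains only
    included, zero-filled, validated records.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    expected = csv_columns()
    cohort = Cohort()
    seen_ids: set[str] = set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing_cols = [c for c in expected if c not in reader.fieldnames]
        if missing_cols:
            raise SchemaError(f"{path}: missing columns {missing_cols}")
        for i, row in enumerate(reader, start=1):
            if any(v is None for v in row.values()):
                cohort.validation_report.append(
                    ValidationIssue(i, row.get("patient_id") or "", "<row>", "truncated row")
                )
                continue
            pid = (row.get("patient_id") or "").strip()
            try:
                rec = _row_to_record(row)
            except _FieldError as e:
                cohort.validation_report.append(ValidationIssue(i, pid, e.fieldname, e.issue))
                continue
            if rec.patient_id in seen_ids:
                cohort.validation_report.append(
                    ValidationIssue(i, rec.patient_id, "patient_id", "duplicate patient_id")
                )
                continue
            seen_ids.add(rec.patient_id)
            included = apply_missing_policy(rec)
            if included is None:
                cohort.validation_report.append(
                    ValidationIssue(
                        i, rec.patient_id, "<cost questions>",
                        "no cost question answered; excluded from denominator",
                    )
                )
                continue
            try:
                included.validate()
            except RecordValidationError as e:
                for issue in e.issues:
                    fieldname = issue.split(":", 1)[0]
                    cohort.validation_report.append(ValidationIssue(i, pid, fieldname, issue))
                continue
            cohort.records.append(included)
    return cohort
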