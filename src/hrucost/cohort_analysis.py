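"""Cohort-level aggregation: utilisation summary, cost components with CIs,
attributable (excess-cost) fractions and subgroup stratification.

Component means are taken over *all* included patients — zeros stay in the
denominator — and every attributable fraction is a ratio of cohort mean
costs (sum of attributable component means over sum of total component
means), not a mean of per-patient ratios; only the ratio-of-means definition
is consistent with reporting excess costs as a share of the average cost.

Money is rendered to 2 decimals and percentages to 1 decimal with half-up
rounding, and only at the report layer; all aggregation is at full floating
precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cost_engine import COMPONENTS, DIRECT_COMPONENTS, CostBreakdown
from .hru_model import (
    Cohort,
    DIAGNOSTIC_MODALITIES,
    Employment,
    OTHER_ITEMS,
    PatientRecord,
    ProductivityLossCategory,
    Sex,
)
from .productivity import AbsenceImputation, impute_absence_days
from .uncertainty import MeanWithCI, mean_ci

__all__ = [
    "CIConfig",
    "ComponentStats",
    "CohortSummary",
    "Classifier",
    "SubgroupSpec",
    "DEFAULT_SUBGROUPS",
    "has_comorbidity",
    "is_fragile",
    "summarise",
    "stratify",
    "round_half_up",
    "table3_dataframe",
    "table4_dataframe",
    "fractions_dict",
    "subgroups_dataframe",
    "breakdowns_dataframe",
]

COMPONENT_LABELS = {
    "anticoagulation": "Costs related to anticoagulation at follow-up",
    "ambulatory_visits": "Costs related to ambulatory visits",
    "rehospitalisation": "Costs related to rehospitalisation",
    "other_medications": "Costs related to medications other than anticoagulation",
    "diagnostics": "Costs related to additional examinations",
    "other_medical": "Costs related to other medical expenses",
    "formal_informal_help": "Costs related to formal and informal help",
    "productivity_loss": "Costs related to productivity loss",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding (what printed clinical tables use)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CIConfig:
    method: str = "auto"  # auto | gamma_glm | bootstrap_percentile
    level: float = 0.95
    bootstrap_reps: int = 2000
    seed: int = 0


@dataclass(frozen=True)
class ComponentStats:
    mean_total: float
    sd_total: Optional[float]
    mean_attributable: float
    sd_attributable: Optional[float]
    ci: Optional[MeanWithCI] = None


@dataclass
class CohortSummary:
    """Cohort means/SDs/CIs per component plus fractions and utilisation."""

    n: int
    per_component: dict[str, ComponentStats] = field(default_factory=dict)
    direct_mean: Optional[float] = None
    indirect_mean: Optional[float] = None
    overall_mean: Optional[float] = None
    direct_attributable_mean: Optional[float] = None
    overall_attributable_mean: Optional[float] = None
    attributable_fraction_overall: Optional[float] = None
    attributable_fraction_direct: Optional[float] = None
    indirect_share_overall: Optional[float] = None
    indirect_share_attributable: Optional[float] = None
    utilisation: dict[str, Optional[float]] = field(default_factory=dict)
    undefined: bool = False  # n == 0: no means are defined


def has_comorbidity(record: PatientRecord) -> bool:
    """At least one of the five tracked comorbidities."""
    return len(record.comorbidities) > 0


def is_fragile(record: PatientRecord) -> bool:
    """Age > 75 y, creatinine clearance < 50 ml/min or BMI < 18.5 kg/m^2.

    All inequalities strict, exactly as the fragility definition states.
    """
    for name in ("age", "creatinine_clearance", "bmi"):
        if getattr(record, name) is None:
            raise ValueError(f"fragility needs {name}; record {record.patient_id} lacks it")
    return record.age > 75 or record.creatinine_clearance < 50 or record.bmi < 18.5


class Classifier(str, enum.Enum):
    AGE_LE65_VS_GT65 = "age_le65_vs_gt65"
    SEX = "sex"
    COMORBIDITY_ANY = "comorbidity_any"
    FRAGILITY = "fragility"


@dataclass(frozen=True)
class SubgroupSpec:
    name: str
    classifier: Classifier

    def stratum(self, record: PatientRecord) -> str:
        c = self.classifier
        if c is Classifier.AGE_LE65_VS_GT65:
            return "age_le65" if record.age <= 65 else "age_gt65"
        if c is Classifier.SEX:
            return "women" if record.sex is Sex.FEMALE else "men"
        if c is Classifier.COMORBIDITY_ANY:
            return "comorbid" if has_comorbidity(record) else "non_comorbid"
        return "fragile" if is_fragile(record) else "non_fragile"

    def strata(self) -> tuple[str, str]:
        return {
            Classifier.AGE_LE65_VS_GT65: ("age_le65", "age_gt65"),
            Classifier.SEX: ("women", "men"),
            Classifier.COMORBIDITY_ANY: ("comorbid", "non_comorbid"),
            Classifier.FRAGILITY: ("fragile", "non_fragile"),
        }[self.classifier]


DEFAULT_SUBGROUPS = (
    SubgroupSpec("age", Classifier.AGE_LE65_VS_GT65),
    SubgroupSpec("sex", Classifier.SEX),
    SubgroupSpec("comorbidity", Classifier.COMORBIDITY_ANY),
    SubgroupSpec("fragility", Classifier.FRAGILITY),
)


def _sd(x: np.ndarray) -> Optional[float]:
    return float(np.std(x, ddof=1)) if x.size >= 2 else None


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def _utilisation(records: Sequence[PatientRecord], imputation: AbsenceImputation) -> dict:
    n = len(records)
    if n == 0:
        return {}
    u: dict[str, Optional[float]] = {}
    visits = np.array([sum(g.count for g in r.ambulatory_visits or ()) for r in records])
    pe_visits = np.array(
        [sum(g.pe_related_count for g in r.ambulatory_visits or ()) for r in records]
    )
    u["ambulatory_any_frac"] = float(np.mean(visits > 0))
    u["ambulatory_pe_any_frac"] = float(np.mean(pe_visits > 0))
    u["ambulatory_visits_mean"] = float(visits.mean())
    u["ambulatory_pe_visits_mean"] = float(pe_visits.mean())
    u["ambulatory_pe_visit_share"] = _ratio(float(pe_visits.mean()), float(visits.mean()))

    hosp_days = np.array(
        [sum(h.length_of_stay for h in r.hospitalisations or ()) for r in records]
    )
    hospitalised = np.array([bool(r.hospitalisations) for r in records])
    pe_hosp = np.array(
        [any(h.pe_related for h in r.hospitalisations or ()) for r in records]
    )
    u["hospitalised_frac"] = float(hospitalised.mean())
    u["hospitalised_pe_frac"] = float(pe_hosp.mean())
    u["los_mean_among_hospitalised"] = (
        float(hosp_days[hospitalised].mean()) if hospitalised.any() else None
    )
    pe_days = np.array(
        [
            sum(h.length_of_stay for h in r.hospitalisations or () if h.pe_related)
            for r in records
        ]
    )
    u["los_pe_mean_among_pe_hospitalised"] = (
        float(pe_days[pe_hosp].mean()) if pe_hosp.any() else None
    )

    help_any = np.array([bool(r.help_visits and r.help_visits.count > 0) for r in records])
    help_days = np.array([(r.help_days.count if r.help_days else 0) for r in records])
    u["help_frac"] = float(help_any.mean())
    u["help_days_mean_among_helped"] = float(help_days[help_any].mean()) if help_any.any() else None

    for setting in ("inpatient", "outpatient"):
        eps = [getattr(r, f"rehab_{setting}") for r in records]
        any_rehab = np.array([bool(e and e.days > 0) for e in eps])
        days = np.array([(e.days if e else 0) for e in eps])
        u[f"rehab_{setting}_frac"] = float(any_rehab.mean())
        u[f"rehab_{setting}_days_mean"] = (
            float(days[any_rehab].mean()) if any_rehab.any() else None
        )

    absent = np.array(
        [
            (r.productivity_loss_category or ProductivityLossCategory.NONE)
            is not ProductivityLossCategory.NONE
            for r in records
        ]
    )
    employed = np.array([r.employed_before_pe is Employment.YES for r in records])
    u["disability_frac"] = float(absent.mean())
    u["absent_among_employed_frac"] = (
        float(absent[employed].mean()) if employed.any() else None
    )
    days = np.array(
        [
            impute_absence_days(
                r.productivity_loss_category or ProductivityLossCategory.NONE, imputation
            )
            for r in records
        ]
    )
    u["disability_days_mean_among_absent"] = float(days[absent].mean()) if absent.any() else None

    for m in DIAGNOSTIC_MODALITIES:
        cnt = np.array([((r.diagnostics or {}).get(m).count if (r.diagnostics or {}).get(m) else 0) for r in records])
        pe = np.array(
            [((r.diagnostics or {}).get(m).pe_related_count if (r.diagnostics or {}).get(m) else 0) for r in records]
        )
        u[f"dx_{m}_mean"] = float(cnt.mean())
        u[f"dx_{m}_pe_mean"] = float(pe.mean())
        u[f"dx_{m}_any_frac"] = float(np.mean(cnt > 0))
    for it in OTHER_ITEMS:
        cnt = np.array([((r.other_items or {}).get(it).count if (r.other_items or {}).get(it) else 0) for r in records])
        pe = np.array(
            [((r.other_items or {}).get(it).pe_related_count if (r.other_items or {}).get(it) else 0) for r in records]
        )
        u[f"other_{it}_mean"] = float(cnt.mean())
        u[f"other_{it}_pe_mean"] = float(pe.mean())
    return u


def summarise(
    cohort: Cohort | Sequence[PatientRecord],
    breakdowns: Sequence[CostBreakdown],
    ci_config: CIConfig = CIConfig(),
    imputation: AbsenceImputation = AbsenceImputation(),
    compute_ci: bool = True,
) -> CohortSummary:
    """Aggregate per-patient breakdowns into the cohort summary.

    ``breakdowns`` must align 1:1 (same patients, same order) with the
    included records of ``cohort``.
    """
    records = list(cohort.records if isinstance(cohort, Cohort) else cohort)
    if len(records) != len(breakdowns):
        raise ValueError(
            f"{len(breakdowns)} breakdowns for {len(records)} records; inputs misaligned"
        )
    for r, b in zip(records, breakdowns):
        if r.patient_id != b.patient_id:
            raise ValueError(
                f"breakdown for {b.patient_id!r} does not match record {r.patient_id!r}"
            )
    n = len(records)
    if n == 0:
        return CohortSummary(n=0, undefined=True)

    summary = CohortSummary(n=n)
    totals_by_comp: dict[str, np.ndarray] = {}
    for ci_seed_offset, comp in enumerate(COMPONENTS):
        totals = np.array([b.components[comp][0] for b in breakdowns])
        attribs = np.array([b.components[comp][1] for b in breakdowns])
        totals_by_comp[comp] = totals
        ci = None
        if compute_ci and n >= 2:
            ci = mean_ci(
                totals,
                level=ci_config.level,
                method=ci_config.method,
                reps=ci_config.bootstrap_reps,
                seed=ci_config.seed + ci_seed_offset,
            )
        summary.per_component[comp] = ComponentStats(
            mean_total=float(totals.mean()),
            sd_total=_sd(totals),
            mean_attributable=float(attribs.mean()),
            sd_attributable=_sd(attribs),
            ci=ci,
        )

    stats = summary.per_component
    summary.direct_mean = sum(stats[c].mean_total for c in DIRECT_COMPONENTS)
    summary.indirect_mean = stats["productivity_loss"].mean_total
    summary.overall_mean = summary.direct_mean + summary.indirect_mean
    summary.direct_attributable_mean = sum(
        stats[c].mean_attributable for c in DIRECT_COMPONENTS
    )
    summary.overall_attributable_mean = (
        summary.direct_attributable_mean + stats["productivity_loss"].mean_attributable
    )
    summary.attributable_fraction_overall = _ratio(
        summary.overall_attributable_mean, summary.overall_mean
    )
    summary.attributable_fraction_direct = _ratio(
        summary.direct_attributable_mean, summary.direct_mean
    )
    summary.indirect_share_overall = _ratio(summary.indirect_mean, summary.overall_mean)
    summary.indirect_share_attributable = _ratio(
        stats["productivity_loss"].mean_attributable, summary.overall_attributable_mean
    )
    summary.utilisation = _utilisation(records, imputation)
    return summary


def stratify(
    cohort: Cohort | Sequence[PatientRecord],
    breakdowns: Sequence[CostBreakdown],
    spec: SubgroupSpec,
    ci_config: CIConfig = CIConfig(),
    imputation: AbsenceImputation = AbsenceImputation(),
    compute_ci: bool = False,
) -> dict[str, CohortSummary]:
    """Per-stratum summaries; the strata partition the cohort exactly.

    An empty stratum yields a summary with ``n=0`` and ``undefined=True``
    rather than NaN-propagated means.
    """
    records = list(cohort.records if isinstance(cohort, Cohort) else cohort)
    if len(records) != len(breakdowns):
        raise ValueError("records and breakdowns misaligned")
    groups: dict[str, tuple[list[PatientRecord], list[CostBreakdown]]] = {
        s: ([], []) for s in spec.strata()
    }
    for r, b in zip(records, breakdowns):
        recs, bds = groups[spec.stratum(r)]
        recs.append(r)
        bds.append(b)
    return {
        s: summarise(recs, bds, ci_config, imputation, compute_ci=compute_ci)
        for s, (recs, bds) in groups.items()
    }


# ----------------------------------------------------------------- reports


def _money(x: Optional[float]) -> str:
    return "" if x is None else f"{round_half_up(x, 2):.2f}"


def _pct(x: Optional[float]) -> str:
    return "" if x is None else f"{round_half_up(100 * x, 1):.1f}"


def table4_dataframe(summary: CohortSummary) -> pd.DataFrame:
    """Eight component rows plus direct/indirect/overall totals, rendered."""
    rows = []
    for comp in COMPONENTS:
        st = summary.per_component[comp]
        rows.append(
            {
                "component": comp,
                "label": COMPONENT_LABELS[comp],
                "costs_overall": _money(st.mean_total),
                "sd_overall": _money(st.sd_total),
                "costs_pe": _money(st.mean_attributable),
                "sd_pe": _money(st.sd_attributable),
                "ci_low": _money(st.ci.ci_low if st.ci else None),
                "ci_high": _money(st.ci.ci_high if st.ci else None),
                "ci_method": st.ci.method.value if st.ci else "",
            }
        )
    for label, total, attrib in (
        ("Direct costs", summary.direct_mean, summary.direct_attributable_mean),
        ("Indirect costs", summary.indirect_mean,
         summary.per_component["productivity_loss"].mean_attributable),
        ("Overall costs", summary.overall_mean, summary.overall_attributable_mean),
    ):
        rows.append(
            {
                "component": label.lower().replace(" ", "_"),
                "label": label,
                "costs_overall": _money(total),
                "sd_overall": "",
                "costs_pe": _money(attrib),
                "sd_pe": "",
                "ci_low": "",
                "ci_high": "",
                "ci_method": "",
            }
        )
    return pd.DataFrame(rows)


def table3_dataframe(summary: CohortSummary) -> pd.DataFrame:
    """Utilisation summary (resource, statistic, value) in canonical order."""
    u = summary.utilisation
    rows = [("n_patients", "count", float(summary.n))]
    rows += [(k, "value", v) for k, v in u.items()]
    return pd.DataFrame(
        [
            {"resource": k, "statistic": s, "value": ("" if v is None else round(v, 6))}
            for k, s, v in rows
        ]
    )


def fractions_dict(summary: CohortSummary) -> dict:
    """Excess-cost and cost-composition shares, raw and as printed percents."""
    raw = {
        "attributable_fraction_overall": summary.attributable_fraction_overall,
        "attributable_fraction_direct": summary.attributable_fraction_direct,
        "indirect_share_overall": summary.indirect_share_overall,
        "indirect_share_attributable": summary.indirect_share_attributable,
    }
    return {
        "n": summary.n,
        "proportions": raw,
        "percent_rendered": {k: _pct(v) for k, v in raw.items()},
    }


def subgroups_dataframe(
    cohort: Cohort | Sequence[PatientRecord],
    breakdowns: Sequence[CostBreakdown],
    specs: Iterable[SubgroupSpec] = DEFAULT_SUBGROUPS,
    include_indirect: bool = False,
    ci_config: CIConfig = CIConfig(),
) -> pd.DataFrame:
    """Direct-cost subgroup table (optionally including indirect costs)."""
    rows = []
    for spec in specs:
        for stratum, s in stratify(cohort, breakdowns, spec, ci_config).items():
            mean = None
            if not s.undefined:
                mean = s.direct_mean + (s.indirect_mean if include_indirect else 0.0)
            rows.append(
                {
                    "subgroup": spec.name,
                    "stratum": stratum,
                    "n": s.n,
                    "mean_cost": _money(mean),
                    "includes_indirect": include_indirect,
                }
            )
    return pd.DataFrame(rows)


def breakdowns_dataframe(breakdowns: Sequence[CostBreakdown]) -> pd.DataFrame:
    """One row per patient: every component (total and PE-attributable)."""
    rows = []
    for b in breakdowns:
        row: dict[str, object] = {"patient_id": b.patient_id}
        for comp in COMPONENTS:
            total, attrib = b.components[comp]
            row[f"{comp}_total"] = total
            row[f"{comp}_pe"] = attrib
        row["direct_total"] = b.direct_total
        row["indirect_total"] = b.indirect_total
        row["overall_total"] = b.overall_total
        row["pe_attributable_total"] = b.pe_attributable_total
        rows.append(row)
    return pd.DataFrame(rows)
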