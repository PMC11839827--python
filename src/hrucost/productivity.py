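"""Indirect (productivity-loss) costs by the human-capital method.

The questionnaire records work absence only as a categorical answer
(none / at most 6 weeks / more than 6 weeks), so absence duration is imputed:
the "≤ 6 weeks" category is valued as 3 weeks of absence and the "> 6 weeks"
category as 9 weeks. Weeks are converted at 7 calendar days per week
(21 and 63 days), and each day of absence is valued at the average labour
cost per calendar day of absence (343.95 € in the shipped 2021 German
registry, item ``productivity_day``).

Productivity costs are assigned only to patients employed before the index
event; an unknown employment status cannot be affirmed as employed and
contributes zero. The full absence is valued with no friction-period cap
(pure human-capital method over the 3-month horizon), and productivity loss
after an acute index event is treated as entirely disease-specific, so the
PE-attributable part always equals the total.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hru_model import Employment, PatientRecord, ProductivityLossCategory
from .unit_costs import UnitCostTable

__all__ = ["AbsenceImputation", "impute_absence_days", "productivity_cost"]

PRODUCTIVITY_ITEM = "productivity_day"


@dataclass(frozen=True)
class AbsenceImputation:
    """Days of absence imputed for each categorical questionnaire answer."""

    le_6_weeks_days: int = 21  # 3 weeks x 7 days
    gt_6_weeks_days: int = 63  # 9 weeks x 7 days

    def __post_init__(self) -> None:
        if not 0 < self.le_6_weeks_days < self.gt_6_weeks_days:
            raise ValueError(
                "imputation must satisfy 0 < le_6_weeks_days < gt_6_weeks_days, "
                f"got {self.le_6_weeks_days} / {self.gt_6_weeks_days}"
            )


def impute_absence_days(
    category: ProductivityLossCategory,
    imputation: AbsenceImputation = AbsenceImputation(),
) -> int:
    """Absence days for a categorical productivity-loss answer."""
    if category is ProductivityLossCategory.NONE:
        return 0
    if category is ProductivityLossCategory.LE_6_WEEKS:
        return imputation.le_6_weeks_days
    return imputation.gt_6_weeks_days


def productivity_cost(
    record: PatientRecord,
    table: UnitCostTable,
    imputation: AbsenceImputation = AbsenceImputation(),
) -> tuple[float, float]:
    """(total €, PE-attributable €) of productivity loss for one patient.

    Zero unless the patient was employed before the event; otherwise
    imputed absence days x the per-day productivity price, fully
    PE-attributable.
    """
    if record.employed_before_pe is not Employment.YES:
        return (0.0, 0.0)
    category = record.productivity_loss_category or ProductivityLossCategory.NONE
    days = impute_absence_days(category, imputation)
    total = days * table.price(PRODUCTIVITY_ITEM)
    return (total, total)
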