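"""Unit-cost registry and currency-year adjustment.

Standardised German unit costs (2021 €) for the resource items recorded by
the post-pulmonary-embolism healthcare resource utilisation questionnaire:
anticoagulant drug-days, inpatient hospital days, diagnostic examinations,
rehabilitation days, formal/informal help visits, sundry medical items and
a per-day valuation of productivity loss. Prices are kept at full floating
precision; rounding to cents happens only when reports are rendered.

Ambulatory physician fees are not part of the fixed registry because German
statutory health insurance reimburses them per specialty; the registry holds
a configurable per-specialty fee map (``ambulatory_visit_<specialty>``
entries) and ships a two-tier general-practitioner/specialist default.

Inflation (CPI) and purchasing-power-parity series are user configuration,
not code constants: :func:`adjust_price` composes arbitrary series.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Unit",
    "UnitCost",
    "UnitCostTable",
    "PriceIndexSeries",
    "MissingPriceError",
    "PriceIndexError",
    "adjust_price",
    "AMBULATORY_FEE_PREFIX",
]

AMBULATORY_FEE_PREFIX = "ambulatory_visit_"


class Unit(str, enum.Enum):
    """Resource dimension a price applies to."""

    PER_DAY = "per_day"
    PER_VISIT = "per_visit"
    PER_EXAMINATION = "per_examination"
    PER_ITEM = "per_item"
    PER_DAY_OF_ABSENCE = "per_day_of_absence"


class MissingPriceError(KeyError):
    """Raised when a resource item has no registered unit cost."""

    def __init__(self, item_id: str):
        super().__init__(item_id)
        self.item_id = item_id

    def __str__(self) -> str:  # KeyError would repr-quote the message
        return f"no unit cost registered for item {self.item_id!r}"


class PriceIndexError(ValueError):
    """Raised for missing years or non-positive factors in a price index."""


@dataclass(frozen=True)
class UnitCost:
    """One registered price: €/unit for a resource item in a price year."""

    item_id: str
    value: float
    unit: Unit
    price_year: int
    country: str = "DE"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"unit cost for {self.item_id!r} must be >= 0, got {self.value}")
        object.__setattr__(self, "unit", Unit(self.unit))


@dataclass
class UnitCostTable:
    """Registry of unit costs keyed by item id.

    Lookup of an unknown item raises :class:`MissingPriceError` — never a
    silent zero — so a costing run cannot drop a resource unnoticed.
    """

    entries: dict[str, UnitCost] = field(default_factory=dict)
    reference_year: int = 2021
    reference_country: str = "DE"

    def lookup(self, item_id: str) -> UnitCost:
        try:
            return self.entries[item_id]
        except KeyError:
            raise MissingPriceError(item_id) from None

    def price(self, item_id: str) -> float:
        """Convenience: the € value of :meth:`lookup`."""
        return self.lookup(item_id).value

    def add(self, cost: UnitCost) -> None:
        self.entries[cost.item_id] = cost

    def fee_schedule(self) -> dict[str, float]:
        """Per-specialty ambulatory visit fees registered in this table."""
        return {
            item_id[len(AMBULATORY_FEE_PREFIX):]: uc.value
            for item_id, uc in self.entries.items()
            if item_id.startswith(AMBULATORY_FEE_PREFIX)
        }

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UnitCostTable":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: Mapping) -> "UnitCostTable":
        table = cls(
            reference_year=int(doc.get("reference_year", 2021)),
            reference_country=str(doc.get("reference_country", "DE")),
        )
        for row in doc["items"]:
            table.add(
                UnitCost(
                    item_id=str(row["item_id"]),
                    value=float(row["value"]),
                    unit=Unit(row["unit"]),
                    price_year=int(row.get("price_year", table.reference_year)),
                    country=str(row.get("country", table.reference_country)),
                )
            )
        return table

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "reference_year": self.reference_year,
            "reference_country": self.reference_country,
            "items": [
                {
                    "item_id": uc.item_id,
                    "value": uc.value,
                    "unit": uc.unit.value,
                    "price_year": uc.price_year,
                    "country": uc.country,
                }
                for uc in self.entries.values()
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def default(cls) -> "UnitCostTable":
        """The shipped German 2021 registry (``table1_2021_de.yaml``)."""
        ref = resources.files("hrucost").joinpath("data/table1_2021_de.yaml")
        with ref.open("r", encoding="utf-8") as fh:
            return cls._from_doc(yaml.safe_load(fh))


@dataclass
class PriceIndexSeries:
    """A CPI or PPP series: positive multiplicative factors by year.

    For CPI the factor is the index level in that year; prices are moved
    between years by the ratio of levels. A PPP conversion is a single
    country-pair factor applied on top (see :func:`adjust_price`).
    """

    kind: str = "cpi"  # {"cpi", "ppp"}
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("cpi", "ppp"):
            raise ValueError(f"kind must be 'cpi' or 'ppp', got {self.kind!r}")
        for year, factor in self.values.items():
            if not factor > 0:
                raise PriceIndexError(f"non-positive factor {factor} for year {year}")

    def factor(self, year: int) -> float:
        try:
            f = self.values[year]
        except KeyError:
            raise PriceIndexError(f"year {year} not present in {self.kind} series") from None
        if not f > 0:
            raise PriceIndexError(f"non-positive factor {f} for year {year}")
        return f

    @classmethod
    def identity(cls, years: range | list[int], kind: str = "cpi") -> "PriceIndexSeries":
        return cls(kind=kind, values={int(y): 1.0 for y in years})


def adjust_price(
    value: float,
    from_year: int,
    cpi: PriceIndexSeries,
    to_year: int,
    ppp_factor: float = 1.0,
) -> float:
    """Move a price between calendar years via a CPI series.

    Returns ``value * cpi[to_year] / cpi[from_year] * ppp_factor``.
    ``ppp_factor`` composes a cross-country purchasing-power conversion
    with the inflation step (1.0 = same country).
    """
    if not ppp_factor > 0:
        raise PriceIndexError(f"non-positive PPP factor {ppp_factor}")
    return value * cpi.factor(to_year) / cpi.factor(from_year) * ppp_factor
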