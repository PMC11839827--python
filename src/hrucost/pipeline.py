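"""End-to-end analysis orchestration with provenance sidecars.

:func:`run_pipeline` ties the stages together — read (or simulate) a cohort,
cost every patient, aggregate, stratify — and writes the report artifacts:

* ``per_patient_costs.csv`` — one cost-breakdown row per patient
* ``table3_utilisation.csv`` — utilisation summary
* ``table4_components.csv`` — cost components with SDs and CIs
* ``fractions.json`` — excess-cost and composition shares
* ``subgroups.csv`` — subgroup direct costs

Every artifact gets a ``.provenance.json`` sidecar (config hash, seed,
package version) so a report can be traced to the exact configuration that
produced it. Outputs are deterministic for a fixed configuration, including
the bootstrap CIs (seeded). On any stage failure partial outputs are removed
and the failing stage named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .cohort_analysis import (
    CIConfig,
    DEFAULT_SUBGROUPS,
    breakdowns_dataframe,
    fractions_dict,
    subgroups_dataframe,
    summarise,
    table3_dataframe,
    table4_dataframe,
)
from .cost_engine import cost_cohort
from .hru_model import Cohort, read_cohort
from .productivity import AbsenceImputation
from .unit_costs import UnitCostTable

__all__ = ["AnalysisConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a report run depends on."""

    cohort_path: str
    output_dir: str
    prices_path: Optional[str] = None  # None -> shipped 2021 German registry
    ci: CIConfig = CIConfig()
    absence_days_le6: int = 21
    absence_days_gt6: int = 63
    include_indirect_in_subgroups: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ci"] = dataclasses.asdict(self.ci)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        ci = CIConfig(**doc.pop("ci", {}))
        return cls(ci=ci, **doc)


def _write_provenance(path: Path, config: AnalysisConfig) -> None:
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {
                "artifact": path.name,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "hrucost_version": __version__,
                "config": config.to_dict(),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )


def run_pipeline(config: AnalysisConfig, cohort: Cohort | None = None) -> list[Path]:
    """Run read -> cost -> aggregate -> report; returns written artifact paths.

    ``cohort`` may be passed directly (e.g. freshly simulated) to skip the
    read stage. Raises :class:`PipelineError` naming the failing stage; any
    partially written outputs are removed first.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)
        _write_provenance(path, config)

    try:
        stage = "read_prices"
        if config.prices_path is None:
            table = UnitCostTable.default()
        elif not Path(config.prices_path).exists():
            raise PipelineError(stage, f"price file not found: {config.prices_path}")
        else:
            table = UnitCostTable.from_yaml(config.prices_path)

        stage = "read_cohort"
        if cohort is None:
            if not Path(config.cohort_path).exists():
                raise PipelineError(stage, f"cohort file not found: {config.cohort_path}")
            cohort = read_cohort(config.cohort_path)

        stage = "cost"
        imputation = AbsenceImputation(config.absence_days_le6, config.absence_days_gt6)
        breakdowns = cost_cohort(cohort.records, table, imputation=imputation)

        stage = "summarise"
        summary = summarise(cohort, breakdowns, config.ci, imputation)

        stage = "report"
        emit(
            "per_patient_costs.csv",
            lambda p: breakdowns_dataframe(breakdowns).to_csv(p, index=False),
        )
        emit(
            "table3_utilisation.csv",
            lambda p: table3_dataframe(summary).to_csv(p, index=False),
        )
        emit(
            "table4_components.csv",
            lambda p: table4_dataframe(summary).to_csv(p, index=False),
        )
        emit(
            "fractions.json",
            lambda p: p.write_text(
                json.dumps(fractions_dict(summary), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            ),
        )
        emit(
            "subgroups.csv",
            lambda p: subgroups_dataframe(
                cohort,
                breakdowns,
                DEFAULT_SUBGROUPS,
                include_indirect=config.include_indirect_in_subgroups,
                ci_config=config.ci,
            ).to_csv(p, index=False),
        )
        return written
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as e:
        _cleanup(written)
        raise PipelineError(stage, str(e)) from e


def _cleanup(written: list[Path]) -> None:
    for path in written:
        for p in (path, path.with_suffix(path.suffix + ".provenance.json")):
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
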