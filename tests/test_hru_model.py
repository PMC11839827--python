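import dataclasses

import pytest

from conftest import make_record
from hrucost.hru_model import (
    AmbulatoryGroup,
    CountWithPE,
    Employment,
    Hospitalisation,
    ProductivityLossCategory,
    apply_missing_policy,
    csv_columns,
    read_cohort,
    write_cohort,
)


def _raw_minimal(**overrides):
    """A record as it comes off the questionnaire: cost fields may be None."""
    rec = make_record(**overrides)
    return rec


class TestMissingPolicy:
    def test_partial_answers_zero_filled_and_included(self):
        raw = dataclasses.replace(
            _raw_minimal(),
            diagnostics=None,  # diagnostics section skipped
            ambulatory_visits=(AmbulatoryGroup("general_practitioner", 2, 1),),
        )
        rec = apply_missing_policy(raw)
        assert rec is not None
        assert all(d.count == 0 for d in rec.diagnostics.values())
        assert rec.ambulatory_visits[0].count == 2
        assert rec.answered_any_cost_question

    def test_nothing_answered_excludes_record(self):
        raw = _raw_minimal()
        for f in raw._COST_FIELDS:
            raw = dataclasses.replace(raw, **{f: None})
        assert apply_missing_policy(raw) is None

    def test_fully_answered_unchanged(self):
        rec = _raw_minimal(anticoagulation_days=90)
        out = apply_missing_policy(rec)
        assert out == dataclasses.replace(rec, answered_any_cost_question=True)

    def test_idempotent(self):
        raw = dataclasses.replace(_raw_minimal(), diagnostics=None, help_visits=None)
        once = apply_missing_policy(raw)
        twice = apply_missing_policy(once)
        assert once == twice


class TestCsvRoundTrip:
    def _records(self):
        return [
            make_record(
                "A1",
                anticoagulation_days=90,
                ambulatory_visits=(
                    AmbulatoryGroup("general_practitioner", 5, 2),
                    AmbulatoryGroup("specialist", 3, 0),
                ),
                hospitalisations=(Hospitalisation(4, True), Hospitalisation(2, False)),
                productivity_loss_category=ProductivityLossCategory.LE_6_WEEKS,
                employed_before_pe=Employment.YES,
            ),
            make_record("A2", age=82.5, help_visits=CountWithPE(10, 4)),
            make_record("A3", other_medications_cost=33.33, other_medications_pe_cost=10.0),
        ]

    def test_three_row_fixture_round_trips_losslessly(self, tmp_path):
        path = tmp_path / "cohort.csv"
        records = [apply_missing_policy(r) for r in self._records()]
        write_cohort(records, path)
        cohort = read_cohort(path)
        assert cohort.n == 3
        assert cohort.validation_report == []
        assert cohort.records == records

    def test_header_schema(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort([], path)
        header = path.read_text().splitlines()[0]
        assert header.split(",") == csv_columns()


class TestValidation:
    def _write_and_read(self, tmp_path, mutate):
        path = tmp_path / "cohort.csv"
        rec = apply_missing_policy(make_record("B1", anticoagulation_days=90))
        write_cohort([rec], path)
        lines = path.read_text().splitlines()
        lines = mutate(lines)
        path.write_text("\n".join(lines) + "\n")
        return read_cohort(path)

    def test_pe_count_exceeding_total_rejected_with_report(self, tmp_path):
        path = tmp_path / "cohort.csv"
        rec = dataclasses.replace(
            apply_missing_policy(make_record("B1")),
            ambulatory_visits=(AmbulatoryGroup("specialist", 1, 5),),
        )
        write_cohort([rec], path)
        cohort = read_cohort(path)
        assert cohort.n == 0
        assert any("pe_related_count" in i.issue for i in cohort.validation_report)
        assert cohort.validation_report[0].row == 1

    def test_duplicate_patient_id_rejected(self, tmp_path):
        path = tmp_path / "cohort.csv"
        rec = apply_missing_policy(make_record("B1", anticoagulation_days=1))
        write_cohort([rec, rec], path)
        cohort = read_cohort(path)
        assert cohort.n == 1
        assert any(i.issue == "duplicate patient_id" for i in cohort.validation_report)

    def test_fractional_days_rejected(self, tmp_path):
        def mutate(lines):
            header = lines[0].split(",")
            row = lines[1].split(",")
            row[header.index("hosp_1_los")] = "3.5"
            row[header.index("hosp_1_pe")] = "1"
            return [lines[0], ",".join(row)]

        cohort = self._write_and_read(tmp_path, mutate)
        assert cohort.n == 0
        assert any("fractional" in i.issue for i in cohort.validation_report)

    def test_invalid_enum_rejected(self, tmp_path):
        def mutate(lines):
            header = lines[0].split(",")
            row = lines[1].split(",")
            row[header.index("sex")] = "diverse"
            return [lines[0], ",".join(row)]

        cohort = self._write_and_read(tmp_path, mutate)
        assert cohort.n == 0
        assert any(i.fieldname == "sex" for i in cohort.validation_report)

    def test_missing_demographic_excluded_with_reason(self, tmp_path):
        def mutate(lines):
            header = lines[0].split(",")
            row = lines[1].split(",")
            row[header.index("bmi")] = ""
            return [lines[0], ",".join(row)]

        cohort = self._write_and_read(tmp_path, mutate)
        assert cohort.n == 0
        assert any(
            i.fieldname == "bmi" and "missing" in i.issue for i in cohort.validation_report
        )

    def test_unanswered_cost_questions_reported_as_exclusion(self, tmp_path):
        path = tmp_path / "cohort.csv"
        raw = make_record("B2")
        for f in raw._COST_FIELDS:
            raw = dataclasses.replace(raw, **{f: None})
        write_cohort([raw], path)
        cohort = read_cohort(path)
        assert cohort.n == 0
        assert any("excluded from denominator" in i.issue for i in cohort.validation_report)
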