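"""Registry domain model: tri-state values, normalisation, oBDS-lite I/O."""

import datetime as dt
import json

import numpy as np
import pytest

from treatcourse.registry import (
    AgeBand,
    AttributeValue,
    DiagnosisEvent,
    MISSING,
    ParseError,
    PatientRecord,
    Radiation,
    RadiotherapyEvent,
    SurgeryEvent,
    SystemicTherapyEvent,
    TreatmentCourse,
    UNRELATED,
    ValidationError,
    ValueState,
    age_band,
    aggregate_radiotherapy,
    classify_surgery_group,
    order_events,
    parse_cohort,
    present,
    write_cohort,
)
from treatcourse.simulate import default_breast_cohort

D1, D2 = dt.date(2019, 3, 1), dt.date(2019, 4, 15)


class TestAttributeValue:
    def test_missing_and_unrelated_carry_no_payload(self):
        with pytest.raises(ValidationError):
            AttributeValue(ValueState.MISSING, 3)
        with pytest.raises(ValidationError):
            AttributeValue(ValueState.UNRELATED, "x")

    def test_present_equality_is_payload_equality(self):
        assert present(2) == present(2)
        assert present(2) != present(3)
        assert MISSING != UNRELATED


@pytest.mark.parametrize(
    "codes, expected",
    [
        (["5-870.1"], present("BCS")),
        (["5-872.0"], present("Mastectomy")),
        (["5-874.2"], present("Mastectomy")),
        (["5-877.1"], present("Mastectomy")),
        (["5-879.0"], present("OtherBreast")),
        (["5-870.1", "5-872.0"], UNRELATED),  # two distinct groups -> ambiguous
        (["1-502"], UNRELATED),  # no breast-surgery prefix matched
        ([], UNRELATED),
        (["5-870.1", "1-502"], present("BCS")),  # accessory codes are ignored
    ],
)
def test_classify_surgery_group(codes, expected):
    assert classify_surgery_group(codes) == expected


def test_surgery_group_is_permutation_invariant():
    rng = np.random.default_rng(0)
    pool = ["5-870.1", "5-872.0", "5-874.1", "5-879.9", "1-502", "5-401"]
    for _ in range(100):
        codes = list(rng.choice(pool, size=rng.integers(0, 5)))
        shuffled = list(codes)
        rng.shuffle(shuffled)
        assert classify_surgery_group(codes) == classify_surgery_group(shuffled)


class TestAggregateRadiotherapy:
    def test_breast_only(self):
        apps, region = aggregate_radiotherapy([Radiation("Percutaneous", "Breast")])
        assert apps == present(frozenset({"Percutaneous"}))
        assert region == present("Breast")

    def test_thorax_dominates_breast(self):
        _, region = aggregate_radiotherapy(
            [Radiation("Percutaneous", "Breast"), Radiation("Contact", "Thorax")]
        )
        assert region == present("Thorax")

    def test_foreign_region_is_unrelated(self):
        _, region = aggregate_radiotherapy(
            [Radiation("Percutaneous", "Breast"), Radiation("Percutaneous", "Axilla")]
        )
        assert region == UNRELATED

    def test_empty_is_missing(self):
        assert aggregate_radiotherapy([]) == (MISSING, MISSING)

    def test_application_types_pool_as_set(self):
        apps, _ = aggregate_radiotherapy(
            [Radiation("Percutaneous", "Breast"), Radiation("Percutaneous", "Breast"),
             Radiation("Contact", "Breast")]
        )
        assert apps == present(frozenset({"Percutaneous", "Contact"}))


class TestOrderEvents:
    def test_sorts_by_date(self):
        s = SurgeryEvent(("5-870.1",), date=D2)
        d = DiagnosisEvent(date=D1)
        assert order_events([s, d]) == [d, s]

    def test_same_day_tie_breaks_by_type_rank(self):
        s = SurgeryEvent(("5-870.1",), date=D1)
        rt = RadiotherapyEvent((Radiation("Percutaneous", "Breast"),), date=D1)
        sy = SystemicTherapyEvent(present("CH"), present("A"), date=D1)
        d = DiagnosisEvent(date=D1)
        assert order_events([sy, rt, s, d]) == [d, s, rt, sy]

    def test_undated_events_sort_last_in_input_order(self):
        a = SystemicTherapyEvent(present("CH"), present("A"), date=None)
        b = SystemicTherapyEvent(present("HO"), present("A"), date=None)
        s = SurgeryEvent(("5-870.1",), date=D1)
        assert order_events([a, b, s]) == [s, a, b]

    def test_empty(self):
        assert order_events([]) == []


def test_course_rejects_two_diagnoses():
    with pytest.raises(ValidationError):
        TreatmentCourse("p", (DiagnosisEvent(date=D1), DiagnosisEvent(date=D2)))


def test_death_before_diagnosis_rejected():
    course = TreatmentCourse.build("p", [DiagnosisEvent(date=D1)])
    with pytest.raises(ValidationError):
        PatientRecord("p", course, D1, death_date=D1 - dt.timedelta(days=1))


class TestParseCohort:
    def _patient(self, **overrides):
        base = {
            "patient_id": "p1",
            "diagnosis_date": "2019-03-01",
            "death_date": None,
            "covariates": {"age": 55, "grading": 2, "uicc": 1, "uicc_substage": "IA",
                           "histology_code": "8500/3"},
            "events": [
                {"type": "diagnosis", "date": "2019-03-01", "uicc_stage": 1, "ecog": 0,
                 "age": 55, "histology_code": "8500/3", "grading": 4}
            ],
        }
        base.update(overrides)
        return base

    def test_minimal_instance(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(json.dumps([self._patient()]))
        records = parse_cohort(path)
        assert len(records) == 1
        assert len(records[0].course) == 1

    def test_unknown_histology_parses_as_unrelated(self, tmp_path):
        patient = self._patient()
        patient["events"][0]["histology_code"] = "8140/3"
        path = tmp_path / "c.json"
        path.write_text(json.dumps([patient]))
        (rec,) = parse_cohort(path)
        diag = rec.course.events[0]
        assert diag.histology == UNRELATED

    def test_absent_fields_become_missing(self, tmp_path):
        patient = self._patient()
        patient["events"][0].pop("ecog")
        patient["events"][0]["uicc_stage"] = None
        path = tmp_path / "c.json"
        path.write_text(json.dumps([patient]))
        (rec,) = parse_cohort(path)
        assert rec.course.events[0].ecog is MISSING
        assert rec.course.events[0].uicc_stage is MISSING

    def test_duplicate_patient_id_rejected(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(json.dumps([self._patient(), self._patient()]))
        with pytest.raises(ValidationError, match="duplicate"):
            parse_cohort(path)

    def test_malformed_event_names_record_and_field(self, tmp_path):
        patient = self._patient()
        patient["events"][0]["type"] = "biopsy"
        path = tmp_path / "c.json"
        path.write_text(json.dumps([patient]))
        with pytest.raises(ParseError, match="p1"):
            parse_cohort(path)

    def test_age_bands(self):
        assert age_band(49) is AgeBand.UNDER_50
        assert age_band(50) is AgeBand.FROM_50_TO_69
        assert age_band(69) is AgeBand.FROM_50_TO_69
        assert age_band(70) is AgeBand.OVER_69


@pytest.mark.parametrize("ext", ["json", "csv"])
def test_round_trip_write_then_parse(tmp_path, ext):
    """A generated cohort survives serialisation structurally unchanged."""
    records, _ = default_breast_cohort(120, seed=9)
    path = tmp_path / f"cohort.{ext}"
    write_cohort(records, path)
    back = parse_cohort(path)
    assert back == records
    # parsing never drops a record
    assert len(back) == len(records)
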