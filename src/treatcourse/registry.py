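"""Domain model and I/O for registry treatment-course data ("oBDS-lite").

A treatment course is the ordered sequence of a patient's registry events:
the initial diagnosis, surgeries, radiotherapies, and systemic therapies.
Every comparable attribute is wrapped in an :class:`AttributeValue`, a
tri-state container distinguishing *present* payloads from *missing*
(undocumented / unknown) and *unrelated* (documented, but outside the set of
values considered meaningful for breast-cancer comparison) values.  Missing
and unrelated values are retained, not dropped: downstream distance
computations assign them the maximum distance so they cannot inflate
similarity.

The oBDS-lite schema implemented here is a deliberately small JSON/CSV
format carrying only the attributes the distance measure uses; it is not the
full German oBDS XML.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

__all__ = [
    "AgeBand",
    "AttributeValue",
    "Covariates",
    "DiagnosisEvent",
    "Event",
    "MISSING",
    "ParseError",
    "PatientRecord",
    "Radiation",
    "RadiotherapyEvent",
    "RegistryError",
    "SurgeryEvent",
    "SystemicTherapyEvent",
    "TreatmentCourse",
    "UNRELATED",
    "ValidationError",
    "ValueState",
    "age_band",
    "aggregate_radiotherapy",
    "classify_surgery_group",
    "order_events",
    "parse_cohort",
    "present",
    "write_cohort",
]


class RegistryError(Exception):
    """Base class for registry-model errors."""


class ParseError(RegistryError):
    """A record in an oBDS-lite file could not be parsed.

    Carries the offending record id (or index) and field name.
    """

    def __init__(self, message: str, record: str = "?", fieldname: str = "?"):
        super().__init__(f"record {record!r}, field {fieldname!r}: {message}")
        self.record = record
        self.fieldname = fieldname


class ValidationError(RegistryError):
    """A parsed record violates a domain invariant."""


# ---------------------------------------------------------------------------
# Tri-state attribute values
# ---------------------------------------------------------------------------


class ValueState(enum.Enum):
    PRESENT = "present"
    MISSING = "missing"
    UNRELATED = "unrelated"


@dataclass(frozen=True)
class AttributeValue:
    """Tri-state attribute wrapper.

    ``MISSING`` and ``UNRELATED`` carry no payload; equality of two
    ``PRESENT`` values is payload equality (dataclass equality).
    """

    state: ValueState
    value: Any = None

    def __post_init__(self) -> None:
        if self.state is not ValueState.PRESENT and self.value is not None:
            raise ValidationError(f"{self.state.value} values carry no payload")

    @property
    def is_present(self) -> bool:
        return self.state is ValueState.PRESENT

    def __repr__(self) -> str:  # compact, for medoid reports and debugging
        if self.is_present:
            return f"Present({self.value!r})"
        return self.state.name.capitalize()


def present(value: Any) -> AttributeValue:
    return AttributeValue(ValueState.PRESENT, value)


MISSING = AttributeValue(ValueState.MISSING)
UNRELATED = AttributeValue(ValueState.UNRELATED)


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Histology codes considered meaningful for distance computation; all other
#: codes map to ``UNRELATED`` at parse time.
HISTOLOGY_CODES: tuple[str, ...] = (
    "8510/3",  # medullary carcinoma
    "8540/3",  # Paget's disease of the breast
    "8530/3",  # inflammatory carcinoma
    "8211/3",  # tubular adenocarcinoma
    "8480/3",  # mucinous adenocarcinoma
    "8500/3",  # invasive ductal carcinoma / NST
)

#: Systemic therapy type codes (missing type is handled as MISSING, the
#: distance matrix carries a dedicated "MI" row for it).
THERAPY_TYPES: tuple[str, ...] = (
    "CH", "HO", "IM", "TS", "CI", "CT", "CIT", "IT", "SC", "AS", "WS", "WW", "OT",
)

TEMPORAL_RELATIONS: tuple[str, ...] = ("A", "N", "I", "O")

APPLICATION_TYPES: tuple[str, ...] = ("Percutaneous", "Metabolic", "Contact", "Other")

SURGERY_GROUPS: tuple[str, ...] = ("BCS", "Mastectomy", "OtherBreast")

#: OPS prefix families defining the three breast-surgery groups.
_SURGERY_PREFIXES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("BCS", ("5-870",)),
    ("Mastectomy", ("5-872", "5-874", "5-877")),
    ("OtherBreast", ("5-879",)),
)

#: Residual-status coding: R0 -> 0, R1(is)/R1(cy+) -> 1, R1 -> 2, R2 -> 3.
RESIDUAL_CODES: Mapping[str, int] = {
    "R0": 0,
    "R1is": 1,
    "R1(is)": 1,
    "R1cy+": 1,
    "R1(cy+)": 1,
    "R1": 2,
    "R2": 3,
}
_RESIDUAL_LABELS = {0: "R0", 1: "R1is", 2: "R1", 3: "R2"}


class AgeBand(str, enum.Enum):
    """Age at diagnosis grouped by screening-eligibility bands."""

    UNDER_50 = "<50"
    FROM_50_TO_69 = "50-69"
    OVER_69 = ">69"


def age_band(age: int) -> AgeBand:
    """Group an integer age at diagnosis: <50, 50-69 (inclusive), >69."""
    if age < 50:
        return AgeBand.UNDER_50
    if age <= 69:
        return AgeBand.FROM_50_TO_69
    return AgeBand.OVER_69


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosisEvent:
    uicc_stage: AttributeValue = MISSING  # ordinal 0..4
    ecog: AttributeValue = MISSING  # ordinal 0..4
    age_group: AttributeValue = MISSING  # AgeBand
    histology: AttributeValue = MISSING  # one of HISTOLOGY_CODES
    grading: AttributeValue = MISSING  # ordinal 0..8
    date: dt.date | None = None

    def __post_init__(self) -> None:
        _check_ordinal(self.uicc_stage, 4, "uicc_stage")
        _check_ordinal(self.ecog, 4, "ecog")
        _check_ordinal(self.grading, 8, "grading")
        if self.histology.is_present and self.histology.value not in HISTOLOGY_CODES:
            raise ValidationError(f"histology code {self.histology.value!r} not in the comparable set")
        if self.age_group.is_present and not isinstance(self.age_group.value, AgeBand):
            raise ValidationError(f"age_group payload must be an AgeBand, got {self.age_group.value!r}")


@dataclass(frozen=True)
class SurgeryEvent:
    procedure_codes: tuple[str, ...] = ()
    residual_status: AttributeValue = MISSING  # ordinal 0..3
    complications: AttributeValue = MISSING  # frozenset of categorical codes
    date: dt.date | None = None

    def __post_init__(self) -> None:
        _check_ordinal(self.residual_status, 3, "residual_status")
        if self.complications.is_present and not isinstance(self.complications.value, frozenset):
            object.__setattr__(
                self,
                "complications",
                present(frozenset(self.complications.value)),
            )

    @property
    def surgery_group(self) -> AttributeValue:
        """Derived surgery group; a pure function of the procedure codes."""
        return classify_surgery_group(self.procedure_codes)


@dataclass(frozen=True)
class Radiation:
    application_type: str  # one of APPLICATION_TYPES
    target_region: str  # free string; "breast"/"thorax" are the comparable ones


@dataclass(frozen=True)
class RadiotherapyEvent:
    radiations: tuple[Radiation, ...] = ()
    temporal_relation: AttributeValue = MISSING  # A/N/I/O
    date: dt.date | None = None

    @property
    def application_types(self) -> AttributeValue:
        return aggregate_radiotherapy(self.radiations)[0]

    @property
    def target_region(self) -> AttributeValue:
        return aggregate_radiotherapy(self.radiations)[1]


@dataclass(frozen=True)
class SystemicTherapyEvent:
    therapy_type: AttributeValue = MISSING  # one of THERAPY_TYPES
    temporal_relation: AttributeValue = MISSING
    date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.therapy_type.is_present and self.therapy_type.value not in THERAPY_TYPES:
            raise ValidationError(f"therapy type {self.therapy_type.value!r} unknown")


Event = DiagnosisEvent | SurgeryEvent | RadiotherapyEvent | SystemicTherapyEvent

#: Same-day tie-break rank: diagnosis logically precedes same-day treatment.
_TYPE_RANK = {DiagnosisEvent: 0, SurgeryEvent: 1, RadiotherapyEvent: 2, SystemicTherapyEvent: 3}


def _check_ordinal(av: AttributeValue, scale_max: int, name: str) -> None:
    if av.is_present and not (isinstance(av.value, int) and 0 <= av.value <= scale_max):
        raise ValidationError(f"{name} payload {av.value!r} outside [0, {scale_max}]")


# ---------------------------------------------------------------------------
# Normalisation helpers
# ---------------------------------------------------------------------------


def classify_surgery_group(codes: Sequence[str]) -> AttributeValue:
    """Derive the surgery group from a surgery's OPS procedure codes.

    Codes are matched against the prefix families 5-870 (BCS), 5-872/5-874/
    5-877 (mastectomy) and 5-879 (other breast surgery).  Codes outside those
    families (e.g. accessory lymphadenectomy codes) are ignored.  Exactly one
    distinct matched group yields a present value; zero or two-plus distinct
    groups make the assignment ambiguous and the group is ``UNRELATED``.
    """
    matched: set[str] = set()
    for code in codes:
        for group, prefixes in _SURGERY_PREFIXES:
            if any(code.startswith(p) for p in prefixes):
                matched.add(group)
    if len(matched) == 1:
        return present(next(iter(matched)))
    return UNRELATED


def aggregate_radiotherapy(
    radiations: Sequence[Radiation],
) -> tuple[AttributeValue, AttributeValue]:
    """Aggregate a radiotherapy's individual radiations.

    Returns ``(application_types, target_region)``:

    * application types are pooled into a set (no radiations -> MISSING);
    * the target region is ``Breast`` if only the breast is irradiated,
      ``Thorax`` if the thorax (possibly alongside the breast) is irradiated,
      and ``UNRELATED`` as soon as any region outside breast/thorax occurs.
    """
    if not radiations:
        return MISSING, MISSING
    app_types = frozenset(r.application_type for r in radiations)
    regions = {r.target_region.strip().lower() for r in radiations}
    if regions <= {"breast"}:
        region = present("Breast")
    elif regions <= {"breast", "thorax"}:
        region = present("Thorax")
    else:
        region = UNRELATED
    return present(app_types), region


def order_events(events: Sequence[Event]) -> list[Event]:
    """Order events chronologically.

    Dated events are sorted by (date, type rank, input position); the type
    rank breaks same-day ties as diagnosis < surgery < radiotherapy <
    systemic therapy.  Events without a date keep their input order and sort
    after all dated events.
    """
    dated = [(e.date, _TYPE_RANK[type(e)], i, e) for i, e in enumerate(events) if e.date is not None]
    undated = [e for e in events if e.date is None]
    dated.sort(key=lambda t: t[:3])
    return [e for *_, e in dated] + undated


# ---------------------------------------------------------------------------
# Courses and patient records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentCourse:
    """One patient's ordered sequence of registry events."""

    patient_id: str
    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        n_diag = sum(isinstance(e, DiagnosisEvent) for e in self.events)
        if n_diag > 1:
            raise ValidationError(f"course {self.patient_id!r} has {n_diag} diagnosis events")

    @classmethod
    def build(cls, patient_id: str, events: Sequence[Event]) -> "TreatmentCourse":
        return cls(patient_id, tuple(order_events(events)))

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class Covariates:
    """Patient-level covariates used by the survival workflow."""

    age: int | None = None
    grading: int | None = None  # G1..G3 as 1..3
    uicc_stage: int | None = None  # main stage 0..4
    uicc_substage: str | None = None  # e.g. "IA", "IIB", "IIIA", "IV"
    histology_code: str | None = None

    @property
    def histology_lobular(self) -> bool:
        return bool(self.histology_code and self.histology_code.startswith("8520"))


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    course: TreatmentCourse
    diagnosis_date: dt.date
    death_date: dt.date | None = None
    covariates: Covariates = field(default_factory=Covariates)

    def __post_init__(self) -> None:
        if self.death_date is not None and self.death_date < self.diagnosis_date:
            raise ValidationError(
                f"patient {self.patient_id!r}: death date precedes diagnosis date"
            )


# ---------------------------------------------------------------------------
# oBDS-lite parsing
# ---------------------------------------------------------------------------

_UNRELATED_TOKEN = "unrelated"  # serialised stand-in for unrelated values


def _parse_ordinal(raw: Any, scale_max: int) -> AttributeValue:
    if raw is None or raw == "":
        return MISSING
    if raw == _UNRELATED_TOKEN:
        return UNRELATED
    try:
        value = int(raw)
    except (TypeError, ValueError):
        return UNRELATED
    if 0 <= value <= scale_max:
        return present(value)
    return UNRELATED


def _parse_categorical(raw: Any, allowed: Iterable[str]) -> AttributeValue:
    if raw is None or raw == "":
        return MISSING
    if raw == _UNRELATED_TOKEN:
        return UNRELATED
    return present(raw) if raw in tuple(allowed) else UNRELATED


def _parse_date(raw: Any, record: str, fieldname: str) -> dt.date | None:
    if raw is None or raw == "":
        return None
    try:
        return dt.date.fromisoformat(str(raw))
    except ValueError as exc:
        raise ParseError(str(exc), record, fieldname) from None


def _parse_event(obj: Mapping[str, Any], record: str) -> Event:
    kind = obj.get("type")
    date = _parse_date(obj.get("date"), record, "date")
    if kind == "diagnosis":
        age_raw = obj.get("age")
        if age_raw is None or age_raw == "":
            age_av = MISSING
        elif age_raw == _UNRELATED_TOKEN:
            age_av = UNRELATED
        else:
            age_av = present(age_band(int(age_raw)))
        return DiagnosisEvent(
            uicc_stage=_parse_ordinal(obj.get("uicc_stage"), 4),
            ecog=_parse_ordinal(obj.get("ecog"), 4),
            age_group=age_av,
            histology=_parse_categorical(obj.get("histology_code"), HISTOLOGY_CODES),
            grading=_parse_ordinal(obj.get("grading"), 8),
            date=date,
        )
    if kind == "surgery":
        raw_res = obj.get("residual_status")
        if isinstance(raw_res, str) and raw_res in RESIDUAL_CODES:
            res = present(RESIDUAL_CODES[raw_res])
        else:
            res = _parse_ordinal(raw_res, 3)
        raw_comp = obj.get("complications")
        if raw_comp is None or raw_comp == "":
            comp = MISSING
        elif raw_comp == _UNRELATED_TOKEN:
            comp = UNRELATED
        else:
            comp = present(frozenset(raw_comp))
        return SurgeryEvent(
            procedure_codes=tuple(obj.get("procedure_codes") or ()),
            residual_status=res,
            complications=comp,
            date=date,
        )
    if kind == "radiotherapy":
        rads = []
        for r in obj.get("radiations") or ():
            app = r.get("application_type")
            rads.append(
                Radiation(
                    application_type=app if app in APPLICATION_TYPES else "Other",
                    target_region=str(r.get("target_region", "")),
                )
            )
        return RadiotherapyEvent(
            radiations=tuple(rads),
            temporal_relation=_parse_categorical(obj.get("temporal_relation"), TEMPORAL_RELATIONS),
            date=date,
        )
    if kind == "systemic":
        return SystemicTherapyEvent(
            therapy_type=_parse_categorical(obj.get("therapy_type"), THERAPY_TYPES),
            temporal_relation=_parse_categorical(obj.get("temporal_relation"), TEMPORAL_RELATIONS),
            date=date,
        )
    raise ParseError(f"unknown event type {kind!r}", record, "type")


def _parse_patient(obj: Mapping[str, Any], index: int) -> PatientRecord:
    pid = obj.get("patient_id")
    if not pid:
        raise ParseError("missing patient_id", f"#{index}", "patient_id")
    pid = str(pid)
    diag_raw = obj.get("diagnosis_date")
    if not diag_raw:
        raise ParseError("missing diagnosis_date", pid, "diagnosis_date")
    diagnosis_date = _parse_date(diag_raw, pid, "diagnosis_date")
    death_date = _parse_date(obj.get("death_date"), pid, "death_date")
    cov_obj = obj.get("covariates") or {}

    def _int_or_none(key: str) -> int | None:
        v = cov_obj.get(key)
        return None if v is None or v == "" else int(v)

    cov = Covariates(
        age=_int_or_none("age"),
        grading=_int_or_none("grading"),
        uicc_stage=_int_or_none("uicc"),
        uicc_substage=cov_obj.get("uicc_substage") or None,
        histology_code=cov_obj.get("histology_code") or None,
    )
    events = [_parse_event(e, pid) for e in obj.get("events") or ()]
    try:
        course = TreatmentCourse.build(pid, events)
        return PatientRecord(pid, course, diagnosis_date, death_date, cov)
    except ValidationError as exc:
        raise ParseError(str(exc), pid, "events") from None


def parse_cohort(path: str | Path) -> list[PatientRecord]:
    """Read an oBDS-lite cohort (``.json`` or long-format ``.csv``).

    Every record is validated against the type invariants; unknown
    categorical payloads become ``UNRELATED``, absent fields become
    ``MISSING``, and each course's events are ordered.  Duplicate patient
    ids raise a :class:`ValidationError`.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        raw_patients = _read_csv_patients(path)
    else:
        with open(path, encoding="utf-8") as fh:
            try:
                raw_patients = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(str(exc), str(path), "<file>") from None
        if not isinstance(raw_patients, list):
            raise ParseError("top level must be a list of patients", str(path), "<file>")
    records = [_parse_patient(obj, i) for i, obj in enumerate(raw_patients)]
    seen: set[str] = set()
    for rec in records:
        if rec.patient_id in seen:
            raise ValidationError(f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)
    return records


# ---------------------------------------------------------------------------
# oBDS-lite serialisation
# ---------------------------------------------------------------------------


def _ser_scalar(av: AttributeValue) -> Any:
    if av.is_present:
        v = av.value
        return v.value if isinstance(v, AgeBand) else v
    return None if av.state is ValueState.MISSING else _UNRELATED_TOKEN


def event_to_dict(event: Event) -> dict[str, Any]:
    date = event.date.isoformat() if event.date else None
    if isinstance(event, DiagnosisEvent):
        # serialise the age group via a representative integer age so the
        # field stays a plain number in the schema
        if event.age_group.is_present:
            age = {AgeBand.UNDER_50: 45, AgeBand.FROM_50_TO_69: 60, AgeBand.OVER_69: 75}[
                event.age_group.value
            ]
        elif event.age_group.state is ValueState.UNRELATED:
            age = _UNRELATED_TOKEN
        else:
            age = None
        return {
            "type": "diagnosis",
            "date": date,
            "uicc_stage": _ser_scalar(event.uicc_stage),
            "ecog": _ser_scalar(event.ecog),
            "age": age,
            "histology_code": _ser_scalar(event.histology),
            "grading": _ser_scalar(event.grading),
        }
    if isinstance(event, SurgeryEvent):
        if event.complications.is_present:
            comp: Any = sorted(event.complications.value)
        else:
            comp = _ser_scalar(event.complications)
        return {
            "type": "surgery",
            "date": date,
            "procedure_codes": list(event.procedure_codes),
            "residual_status": _ser_scalar(event.residual_status),
            "complications": comp,
        }
    if isinstance(event, RadiotherapyEvent):
        return {
            "type": "radiotherapy",
            "date": date,
            "radiations": [
                {"application_type": r.application_type, "target_region": r.target_region}
                for r in event.radiations
            ],
            "temporal_relation": _ser_scalar(event.temporal_relation),
        }
    if isinstance(event, SystemicTherapyEvent):
        return {
            "type": "systemic",
            "date": date,
            "therapy_type": _ser_scalar(event.therapy_type),
            "temporal_relation": _ser_scalar(event.temporal_relation),
        }
    raise TypeError(f"unknown event {event!r}")


def record_to_dict(record: PatientRecord) -> dict[str, Any]:
    cov = record.covariates
    return {
        "patient_id": record.patient_id,
        "diagnosis_date": record.diagnosis_date.isoformat(),
        "death_date": record.death_date.isoformat() if record.death_date else None,
        "covariates": {
            "age": cov.age,
            "grading": cov.grading,
            "uicc": cov.uicc_stage,
            "uicc_substage": cov.uicc_substage,
            "histology_code": cov.histology_code,
        },
        "events": [event_to_dict(e) for e in record.course.events],
    }


_CSV_COLUMNS = [
    "patient_id", "diagnosis_date", "death_date",
    "cov_age", "cov_grading", "cov_uicc", "cov_uicc_substage", "cov_histology_code",
    "event_index", "event_type", "event_date",
    "uicc_stage", "ecog", "age", "histology_code", "grading",
    "procedure_codes", "residual_status", "complications",
    "radiations", "temporal_relation", "therapy_type",
]


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort as oBDS-lite JSON or long-format CSV (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_csv(records, path)
        return
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([record_to_dict(r) for r in records], fh, indent=1)
        fh.write("\n")


def _join(values: Any) -> str:
    return ";".join(values) if isinstance(values, list) else ("" if values is None else str(values))


def _write_csv(records: Sequence[PatientRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            base = record_to_dict(rec)
            cov = base["covariates"]
            patient_cols = {
                "patient_id": base["patient_id"],
                "diagnosis_date": base["diagnosis_date"],
                "death_date": base["death_date"] or "",
                "cov_age": cov["age"] if cov["age"] is not None else "",
                "cov_grading": cov["grading"] if cov["grading"] is not None else "",
                "cov_uicc": cov["uicc"] if cov["uicc"] is not None else "",
                "cov_uicc_substage": cov["uicc_substage"] or "",
                "cov_histology_code": cov["histology_code"] or "",
            }
            events = base["events"] or [None]
            for i, ev in enumerate(events):
                row = dict.fromkeys(_CSV_COLUMNS, "")
                row.update(patient_cols)
                if ev is None:
                    row["event_index"] = ""
                    writer.writerow(row)
                    continue
                row["event_index"] = i
                row["event_type"] = ev["type"]
                row["event_date"] = ev["date"] or ""
                for key in ("uicc_stage", "ecog", "age", "histology_code", "grading",
                            "residual_status", "temporal_relation", "therapy_type"):
                    if key in ev and ev[key] is not None:
                        row[key] = ev[key]
                if ev["type"] == "surgery":
                    row["procedure_codes"] = _join(ev["procedure_codes"])
                    comp = ev["complications"]
                    # "[]" marks a documented-empty list; "" marks missing
                    row["complications"] = "[]" if comp == [] else _join(comp)
                if ev["type"] == "radiotherapy":
                    row["radiations"] = "|".join(
                        f"{r['application_type']}:{r['target_region']}" for r in ev["radiations"]
                    )
                writer.writerow(row)


def _read_csv_patients(path: Path) -> list[dict[str, Any]]:
    patients: dict[str, dict[str, Any]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["patient_id"]
            if pid not in patients:
                order.append(pid)
                patients[pid] = {
                    "patient_id": pid,
                    "diagnosis_date": row["diagnosis_date"],
                    "death_date": row["death_date"] or None,
                    "covariates": {
                        "age": row["cov_age"] or None,
                        "grading": row["cov_grading"] or None,
                        "uicc": row["cov_uicc"] or None,
                        "uicc_substage": row["cov_uicc_substage"] or None,
                        "histology_code": row["cov_histology_code"] or None,
                    },
                    "events": [],
                }
            if row["event_type"] == "":
                continue
            ev: dict[str, Any] = {"type": row["event_type"], "date": row["event_date"] or None}
            if row["event_type"] == "diagnosis":
                for key in ("uicc_stage", "ecog", "age", "histology_code", "grading"):
                    ev[key] = row[key] or None
            elif row["event_type"] == "surgery":
                ev["procedure_codes"] = row["procedure_codes"].split(";") if row["procedure_codes"] else []
                ev["residual_status"] = row["residual_status"] or None
                comp = row["complications"]
                if comp == _UNRELATED_TOKEN:
                    ev["complications"] = comp
                elif comp == "[]" or comp == "":
                    # empty string is ambiguous in CSV; the writer emits "[]"
                    # for an explicitly empty, documented complication list
                    ev["complications"] = [] if comp == "[]" else None
                else:
                    ev["complications"] = comp.split(";")
            elif row["event_type"] == "radiotherapy":
                rads = []
                if row["radiations"]:
                    for part in row["radiations"].split("|"):
                        app, _, region = part.partition(":")
                        rads.append({"application_type": app, "target_region": region})
                ev["radiations"] = rads
                ev["temporal_relation"] = row["temporal_relation"] or None
            elif row["event_type"] == "systemic":
                ev["therapy_type"] = row["therapy_type"] or None
                ev["temporal_relation"] = row["temporal_relation"] or None
            patients[pid]["events"].append(ev)
    return [patients[pid] for pid in order]
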