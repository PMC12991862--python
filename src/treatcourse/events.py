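"""Attribute- and event-level distances on the [0, 1] scale.

Every attribute distance maps into [0, 1].  Missing and unrelated values
always take the maximum distance of 1 -- including against themselves -- so
that undocumented information never makes two courses look more alike.  An
event-level distance is the weighted average of its attribute distances;
events of different types are incomparable and are assigned distance 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .registry import (
    AttributeValue,
    DiagnosisEvent,
    Event,
    RadiotherapyEvent,
    SurgeryEvent,
    SystemicTherapyEvent,
)

__all__ = [
    "AttributeWeights",
    "DEFAULT_WEIGHTS",
    "TherapyTypeMatrix",
    "categorical_distance",
    "default_therapy_matrix",
    "diagnosis_distance",
    "event_distance",
    "jaccard_distance",
    "ordinal_distance",
    "radiotherapy_distance",
    "region_distance",
    "surgery_distance",
    "systemic_distance",
]

#: Ordinal attribute ranges used for normalisation.
UICC_SCALE = 4
ECOG_SCALE = 4
GRADING_SCALE = 8
RESIDUAL_SCALE = 3


@dataclass(frozen=True)
class AttributeWeights:
    """Per-event-type attribute weight vectors; each must sum to 1.

    Defaults: systemic therapy weighs the therapy type at 0.7 and the
    temporal relation to primary surgery at 0.3; surgery weighs the
    procedure group at 0.5 and residual status / complications at 0.25
    each; radiotherapy weighs the target region at 0.5 and application
    types / temporal relation at 0.25 each; the five diagnosis attributes
    are weighted equally.
    """

    systemic: tuple[float, float] = (0.7, 0.3)
    surgery: tuple[float, float, float] = (0.5, 0.25, 0.25)
    radiotherapy: tuple[float, float, float] = (0.5, 0.25, 0.25)
    diagnosis: tuple[float, float, float, float, float] = (0.2,) * 5

    def __post_init__(self) -> None:
        for name in ("systemic", "surgery", "radiotherapy", "diagnosis"):
            vec = getattr(self, name)
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights {vec} do not sum to 1")
            if any(w < 0 for w in vec):
                raise ValueError(f"{name} weights {vec} contain negative entries")


DEFAULT_WEIGHTS = AttributeWeights()


class TherapyTypeMatrix:
    """Expert-defined distance matrix over the 14 systemic-therapy codes.

    The 14th code, ``MI``, stands for a missing therapy type: its whole row
    and column -- including the diagonal -- are 1, so missing types keep the
    maximum distance even from each other.
    """

    def __init__(self, labels: tuple[str, ...], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.array_equal(values, values.T):
            raise ValueError("therapy-type matrix must be symmetric")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("therapy-type distances must lie in [0, 1]")
        mi = labels.index("MI")
        diag = np.diag(values)
        if not (np.all(np.delete(diag, mi) == 0) and diag[mi] == 1):
            raise ValueError("diagonal must be 0 except for the MI cell")
        if not (np.all(values[mi] == 1) and np.all(values[:, mi] == 1)):
            raise ValueError("MI row/column must be all 1")
        self.labels = labels
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}
        self._mi = mi

    @classmethod
    def from_csv(cls, path: str | Path) -> "TherapyTypeMatrix":
        """Load a matrix from CSV (decimal commas are normalised to points)."""
        with open(path, encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        labels = tuple(rows[0][1:])
        values = np.array(
            [[float(cell.replace(",", ".")) for cell in row[1:]] for row in rows[1:]]
        )
        return cls(labels, values)

    def distance(self, a: AttributeValue, b: AttributeValue) -> float:
        """Distance between two therapy-type attribute values.

        Missing and unrelated types route through the MI row (all 1).
        """
        ia = self._index[a.value] if a.is_present else self._mi
        ib = self._index[b.value] if b.is_present else self._mi
        return float(self.values[ia, ib])


@lru_cache(maxsize=1)
def default_therapy_matrix() -> TherapyTypeMatrix:
    ref = resources.files("treatcourse.data") / "systemic_therapy_distance.csv"
    with resources.as_file(ref) as path:
        return TherapyTypeMatrix.from_csv(path)


# ---------------------------------------------------------------------------
# Attribute-level distances
# ---------------------------------------------------------------------------


def ordinal_distance(a: AttributeValue, b: AttributeValue, scale_max: int) -> float:
    """Normalised distance |a - b| / scale_max between ordinal values."""
    if scale_max < 1:
        raise ValueError("scale_max must be >= 1")
    if not (a.is_present and b.is_present):
        return 1.0
    for av in (a, b):
        if not 0 <= av.value <= scale_max:
            raise ValueError(f"ordinal payload {av.value} outside [0, {scale_max}]")
    return abs(a.value - b.value) / scale_max


def categorical_distance(a: AttributeValue, b: AttributeValue) -> float:
    """0 for identical present values, 1 otherwise."""
    if a.is_present and b.is_present and a.value == b.value:
        return 0.0
    return 1.0


def jaccard_distance(a: AttributeValue, b: AttributeValue) -> float:
    """Jaccard distance between two present sets; two documented-empty sets
    agree (distance 0), whereas a missing set keeps distance 1."""
    if not (a.is_present and b.is_present):
        return 1.0
    sa, sb = frozenset(a.value), frozenset(b.value)
    if not sa and not sb:
        return 0.0
    return 1.0 - len(sa & sb) / len(sa | sb)


def region_distance(a: AttributeValue, b: AttributeValue) -> float:
    """Aggregated target-region distance: 0 for identical values, 0.5
    between 'Breast' and 'Thorax', 1 for missing/unrelated."""
    if not (a.is_present and b.is_present):
        return 1.0
    if a.value == b.value:
        return 0.0
    if {a.value, b.value} == {"Breast", "Thorax"}:
        return 0.5
    return 1.0


# ---------------------------------------------------------------------------
# Event-level distances
# ---------------------------------------------------------------------------


def diagnosis_distance(
    a: DiagnosisEvent, b: DiagnosisEvent, weights: AttributeWeights = DEFAULT_WEIGHTS
) -> float:
    w = weights.diagnosis
    return (
        w[0] * ordinal_distance(a.uicc_stage, b.uicc_stage, UICC_SCALE)
        + w[1] * ordinal_distance(a.ecog, b.ecog, ECOG_SCALE)
        + w[2] * categorical_distance(a.age_group, b.age_group)
        + w[3] * categorical_distance(a.histology, b.histology)
        + w[4] * ordinal_distance(a.grading, b.grading, GRADING_SCALE)
    )


def systemic_distance(
    a: SystemicTherapyEvent,
    b: SystemicTherapyEvent,
    matrix: TherapyTypeMatrix | None = None,
    weights: AttributeWeights = DEFAULT_WEIGHTS,
) -> float:
    matrix = matrix or default_therapy_matrix()
    w = weights.systemic
    return w[0] * matrix.distance(a.therapy_type, b.therapy_type) + w[1] * categorical_distance(
        a.temporal_relation, b.temporal_relation
    )


def surgery_distance(
    a: SurgeryEvent, b: SurgeryEvent, weights: AttributeWeights = DEFAULT_WEIGHTS
) -> float:
    w = weights.surgery
    return (
        w[0] * categorical_distance(a.surgery_group, b.surgery_group)
        + w[1] * ordinal_distance(a.residual_status, b.residual_status, RESIDUAL_SCALE)
        + w[2] * jaccard_distance(a.complications, b.complications)
    )


def radiotherapy_distance(
    a: RadiotherapyEvent, b: RadiotherapyEvent, weights: AttributeWeights = DEFAULT_WEIGHTS
) -> float:
    w = weights.radiotherapy
    return (
        w[0] * region_distance(a.target_region, b.target_region)
        + w[1] * jaccard_distance(a.application_types, b.application_types)
        + w[2] * categorical_distance(a.temporal_relation, b.temporal_relation)
    )


def event_distance(
    a: Event,
    b: Event,
    matrix: TherapyTypeMatrix | None = None,
    weights: AttributeWeights = DEFAULT_WEIGHTS,
) -> float:
    """Dispatch to the per-type distance; different types are incomparable
    and get the maximum distance 1."""
    if type(a) is not type(b):
        return 1.0
    if isinstance(a, DiagnosisEvent):
        return diagnosis_distance(a, b, weights)
    if isinstance(a, SurgeryEvent):
        return surgery_distance(a, b, weights)
    if isinstance(a, RadiotherapyEvent):
        return radiotherapy_distance(a, b, weights)
    if isinstance(a, SystemicTherapyEvent):
        return systemic_distance(a, b, matrix, weights)
    raise TypeError(f"unsupported event type {type(a).__name__}")


# ---------------------------------------------------------------------------
# Vectorised pairwise event distances (used for whole-cohort matrices)
# ---------------------------------------------------------------------------

# Encoding: present payloads map to codes >= 0, MISSING to -1, UNRELATED to -2.
_MISS, _UNREL = -1, -2


def _code(av: AttributeValue, mapping: dict) -> int:
    if not av.is_present:
        return _MISS if av.state.name == "MISSING" else _UNREL
    return mapping.setdefault(av.value, len(mapping))


def distance_key(event: Event) -> tuple:
    """Hashable identity of an event for distance purposes (ignores dates)."""
    if isinstance(event, DiagnosisEvent):
        return ("D", event.uicc_stage, event.ecog, event.age_group, event.histology, event.grading)
    if isinstance(event, SurgeryEvent):
        return ("S", event.surgery_group, event.residual_status, event.complications)
    if isinstance(event, RadiotherapyEvent):
        return ("R", event.target_region, event.application_types, event.temporal_relation)
    if isinstance(event, SystemicTherapyEvent):
        return ("T", event.therapy_type, event.temporal_relation)
    raise TypeError(f"unsupported event type {type(event).__name__}")


def _ordinal_block(a: np.ndarray, scale: int) -> np.ndarray:
    both = (a[:, None] >= 0) & (a[None, :] >= 0)
    return np.where(both, np.abs(a[:, None] - a[None, :]) / scale, 1.0)


def _categorical_block(a: np.ndarray) -> np.ndarray:
    same = (a[:, None] >= 0) & (a[:, None] == a[None, :])
    return np.where(same, 0.0, 1.0)


def _set_block(codes: np.ndarray, sets: list[frozenset]) -> np.ndarray:
    # small Jaccard matrix over the distinct sets, then a fancy-index expand
    k = len(sets)
    jm = np.ones((k + 2, k + 2))  # trailing rows for the MISS/UNREL codes
    for i in range(k):
        for j in range(i, k):
            si, sj = sets[i], sets[j]
            if not si and not sj:
                d = 0.0
            else:
                d = 1.0 - len(si & sj) / len(si | sj)
            jm[i, j] = jm[j, i] = d
    return jm[codes[:, None], codes[None, :]]


def _region_block(a: np.ndarray) -> np.ndarray:
    # codes: Breast=0, Thorax=1, negatives missing/unrelated
    both = (a[:, None] >= 0) & (a[None, :] >= 0)
    same = a[:, None] == a[None, :]
    return np.where(both, np.where(same, 0.0, 0.5), 1.0)


def pairwise_event_block(
    events: list[Event],
    matrix: TherapyTypeMatrix | None = None,
    weights: AttributeWeights = DEFAULT_WEIGHTS,
) -> np.ndarray:
    """Distance matrix over a list of *same-type* events, vectorised.

    Semantically identical to calling :func:`event_distance` on every pair;
    used to build whole-cohort distance matrices efficiently.
    """
    if not events:
        return np.zeros((0, 0))
    kind = type(events[0])
    if any(type(e) is not kind for e in events):
        raise ValueError("pairwise_event_block requires events of a single type")
    matrix = matrix or default_therapy_matrix()

    if kind is DiagnosisEvent:
        maps: list[dict] = [{}, {}]
        uicc = np.array([e.uicc_stage.value if e.uicc_stage.is_present else _MISS for e in events])
        ecog = np.array([e.ecog.value if e.ecog.is_present else _MISS for e in events])
        grad = np.array([e.grading.value if e.grading.is_present else _MISS for e in events])
        age = np.array([_code(e.age_group, maps[0]) for e in events])
        hist = np.array([_code(e.histology, maps[1]) for e in events])
        w = weights.diagnosis
        return (
            w[0] * _ordinal_block(uicc, UICC_SCALE)
            + w[1] * _ordinal_block(ecog, ECOG_SCALE)
            + w[2] * _categorical_block(age)
            + w[3] * _categorical_block(hist)
            + w[4] * _ordinal_block(grad, GRADING_SCALE)
        )
    if kind is SystemicTherapyEvent:
        mi = matrix.labels.index("MI")
        idx = np.array(
            [matrix._index[e.therapy_type.value] if e.therapy_type.is_present else mi for e in events]
        )
        tmap: dict = {}
        temp = np.array([_code(e.temporal_relation, tmap) for e in events])
        w = weights.systemic
        return w[0] * matrix.values[idx[:, None], idx[None, :]] + w[1] * _categorical_block(temp)
    if kind is SurgeryEvent:
        gmap: dict = {}
        grp = np.array([_code(e.surgery_group, gmap) for e in events])
        res = np.array(
            [e.residual_status.value if e.residual_status.is_present else _MISS for e in events]
        )
        sets: list[frozenset] = []
        smap: dict = {}
        for e in events:
            if e.complications.is_present and e.complications.value not in smap:
                smap[e.complications.value] = len(sets)
                sets.append(e.complications.value)
        # absent sets route to the all-ones padding row past the real sets
        comp = np.array(
            [smap[e.complications.value] if e.complications.is_present else len(sets) for e in events]
        )
        w = weights.surgery
        return (
            w[0] * _categorical_block(grp)
            + w[1] * _ordinal_block(res, RESIDUAL_SCALE)
            + w[2] * _set_block(comp, sets)
        )
    if kind is RadiotherapyEvent:
        regmap = {"Breast": 0, "Thorax": 1}
        reg = np.array(
            [regmap[e.target_region.value] if e.target_region.is_present else _MISS for e in events]
        )
        sets = []
        smap = {}
        apps = [e.application_types for e in events]
        for av in apps:
            if av.is_present and av.value not in smap:
                smap[av.value] = len(sets)
                sets.append(av.value)
        app = np.array([smap[av.value] if av.is_present else len(sets) for av in apps])
        tmap = {}
        temp = np.array([_code(e.temporal_relation, tmap) for e in events])
        w = weights.radiotherapy
        return (
            w[0] * _region_block(reg)
            + w[1] * _set_block(app, sets)
            + w[2] * _categorical_block(temp)
        )
    raise TypeError(f"unsupported event type {kind.__name__}")
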