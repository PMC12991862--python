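"""Shared fixtures: random event builders and the planted-cohort pipeline."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from treatcourse.registry import (
    AgeBand,
    AttributeValue,
    DiagnosisEvent,
    HISTOLOGY_CODES,
    MISSING,
    Radiation,
    RadiotherapyEvent,
    SurgeryEvent,
    SystemicTherapyEvent,
    THERAPY_TYPES,
    TreatmentCourse,
    UNRELATED,
    present,
)

_DATE = dt.date(2019, 6, 1)


def _rand_av(rng: np.random.Generator, draw, p_missing=0.15, p_unrelated=0.10) -> AttributeValue:
    u = rng.random()
    if u < p_missing:
        return MISSING
    if u < p_missing + p_unrelated:
        return UNRELATED
    return present(draw())


def random_event(rng: np.random.Generator, kind: int | None = None):
    """A random event of a random type, with missing/unrelated states mixed in."""
    kind = rng.integers(0, 4) if kind is None else kind
    if kind == 0:
        return DiagnosisEvent(
            uicc_stage=_rand_av(rng, lambda: int(rng.integers(0, 5))),
            ecog=_rand_av(rng, lambda: int(rng.integers(0, 5))),
            age_group=_rand_av(rng, lambda: list(AgeBand)[rng.integers(0, 3)]),
            histology=_rand_av(rng, lambda: HISTOLOGY_CODES[rng.integers(0, 6)]),
            grading=_rand_av(rng, lambda: int(rng.integers(0, 9))),
            date=_DATE,
        )
    if kind == 1:
        codes = []
        if rng.random() < 0.8:
            codes.append(str(rng.choice(["5-870.1", "5-872.0", "5-874.2", "5-879.0", "1-502"])))
        if rng.random() < 0.2:
            codes.append(str(rng.choice(["5-870.2", "5-872.1"])))
        return SurgeryEvent(
            procedure_codes=tuple(codes),
            residual_status=_rand_av(rng, lambda: int(rng.integers(0, 4))),
            complications=_rand_av(
                rng,
                lambda: frozenset(
                    str(c) for c in rng.choice(["BLU", "INF", "SER"], size=rng.integers(0, 3), replace=False)
                ),
            ),
            date=_DATE,
        )
    if kind == 2:
        n_rad = int(rng.integers(0, 3))
        rads = tuple(
            Radiation(
                str(rng.choice(["Percutaneous", "Metabolic", "Contact", "Other"])),
                str(rng.choice(["Breast", "Thorax", "Axilla"])),
            )
            for _ in range(n_rad)
        )
        return RadiotherapyEvent(
            radiations=rads,
            temporal_relation=_rand_av(rng, lambda: str(rng.choice(["A", "N", "I", "O"]))),
            date=_DATE,
        )
    return SystemicTherapyEvent(
        therapy_type=_rand_av(rng, lambda: str(rng.choice(THERAPY_TYPES)), p_unrelated=0.0),
        temporal_relation=_rand_av(rng, lambda: str(rng.choice(["A", "N", "I", "O"]))),
        date=_DATE,
    )


def random_course(rng: np.random.Generator, patient_id: str, max_events: int = 4) -> TreatmentCourse:
    n = int(rng.integers(0, max_events + 1))
    events = []
    if n > 0 and rng.random() < 0.7:
        events.append(random_event(rng, kind=0))  # at most one diagnosis per course
    while len(events) < n:
        events.append(random_event(rng, kind=int(rng.integers(1, 4))))
    return TreatmentCourse.build(patient_id, events)


def brute_force_edit_cost(a, b, cost) -> float:
    """Exhaustive minimum over all edit scripts (independent of the DP)."""

    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a):
            options.append(1.0 + rec(i + 1, j))
        if j < len(b):
            options.append(1.0 + rec(i, j + 1))
        if i < len(a) and j < len(b):
            options.append(cost(a[i], b[j]) + rec(i + 1, j + 1))
        return min(options)

    return rec(0, 0)


def km_product_limit(times, events, horizon) -> float:
    """Hand-rolled product-limit estimate S(horizon)."""
    s = 1.0
    for u in sorted({t for t, e in zip(times, events) if e}):
        if u > horizon:
            break
        at_risk = sum(t >= u for t in times)
        deaths = sum(t == u and e for t, e in zip(times, events))
        s *= 1.0 - deaths / at_risk
    return s


@pytest.fixture(scope="session")
def planted_run():
    """Full pipeline on the planted default cohort (n=1000, seed 42, no
    implausible archetype): records, truth, matrix, embedding, grid search."""
    from treatcourse.clustering import COARSE, EmbeddingConfig, embed, grid_search
    from treatcourse.sequences import pairwise_matrix
    from treatcourse.simulate import default_breast_cohort

    records, truth = default_breast_cohort(1000, seed=42, implausible_weight=0.0)
    matrix = pairwise_matrix([r.course for r in records])
    embedding = embed(matrix, EmbeddingConfig())
    search = grid_search(embedding, COARSE)
    return records, truth, matrix, embedding, search


@pytest.fixture(scope="session")
def cohort10k():
    from treatcourse.simulate import default_breast_cohort

    return default_breast_cohort(10_000, seed=42)
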