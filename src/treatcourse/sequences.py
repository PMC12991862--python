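"""Length-normalised modified Levenshtein distance over treatment courses.

Insertions and deletions cost 1; a substitution costs the event-level
distance between the two events (so substituting an event for a similar one
is cheap, and substituting across event types costs the full 1).  The total
edit cost is divided by the length of the longer course, keeping the result
in [0, 1] regardless of sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .events import (
    AttributeWeights,
    DEFAULT_WEIGHTS,
    TherapyTypeMatrix,
    distance_key,
    event_distance,
    pairwise_event_block,
)
from .registry import TreatmentCourse

__all__ = [
    "DistanceMatrix",
    "course_distance",
    "levenshtein_dp",
    "medoid",
    "nearest_and_farthest",
    "pairwise_matrix",
]


@dataclass(frozen=True, eq=False)
class DistanceMatrix:
    """Symmetric pairwise course-distance matrix with course identifiers.

    The diagonal is forced to 0 even though a course containing missing
    attributes has a positive semantic self-distance (available through
    :func:`course_distance`); downstream embedding requires a zero diagonal.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("matrix must be square and match the id list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < 0) or np.any(v > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")
        v = np.asarray((v + v.T) / 2.0)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {pid: i for i, pid in enumerate(self.ids)})

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, patient_id: str) -> int:
        return self._index[patient_id]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def levenshtein_dp(
    n: int, m: int, substitution_cost: Callable[[int, int], float]
) -> float:
    """Edit-distance dynamic programme with unit indel cost.

    ``substitution_cost(i, j)`` gives the cost of substituting element ``i``
    of the first sequence (0-based) with element ``j`` of the second.
    Returns the unnormalised minimum edit cost.
    """
    prev = [float(j) for j in range(m + 1)]
    for i in range(1, n + 1):
        curr = [float(i)] + [0.0] * m
        for j in range(1, m + 1):
            curr[j] = min(
                prev[j] + 1.0,
                curr[j - 1] + 1.0,
                prev[j - 1] + substitution_cost(i - 1, j - 1),
            )
        prev = curr
    return prev[m]


def course_distance(
    a: TreatmentCourse,
    b: TreatmentCourse,
    matrix: TherapyTypeMatrix | None = None,
    weights: AttributeWeights = DEFAULT_WEIGHTS,
) -> float:
    """Normalised modified Levenshtein distance between two courses.

    The raw edit cost is divided by max(len(a), len(b)); two empty courses
    have distance 0 (the limit of identical sequences).
    """
    if len(a) == 0 and len(b) == 0:
        return 0.0
    cost = levenshtein_dp(
        len(a),
        len(b),
        lambda i, j: event_distance(a.events[i], b.events[j], matrix, weights),
    )
    return cost / max(len(a), len(b))


# ---------------------------------------------------------------------------
# Whole-cohort matrices
# ---------------------------------------------------------------------------


def _tokenize(
    courses: Sequence[TreatmentCourse],
    matrix: TherapyTypeMatrix | None,
    weights: AttributeWeights,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Map every event to a vocabulary index and build the vocabulary's
    pairwise event-distance matrix (cross-type entries are 1)."""
    vocab_index: dict[tuple, int] = {}
    vocab_events: list = []
    token_seqs: list[np.ndarray] = []
    for course in courses:
        toks = []
        for event in course.events:
            key = distance_key(event)
            idx = vocab_index.get(key)
            if idx is None:
                idx = len(vocab_events)
                vocab_index[key] = idx
                vocab_events.append(event)
            toks.append(idx)
        token_seqs.append(np.asarray(toks, dtype=np.intp))
    v = len(vocab_events)
    ev_d = np.ones((max(v, 1), max(v, 1)))
    by_type: dict[type, list[int]] = {}
    for i, ev in enumerate(vocab_events):
        by_type.setdefault(type(ev), []).append(i)
    for indices in by_type.values():
        block = pairwise_event_block([vocab_events[i] for i in indices], matrix, weights)
        ev_d[np.ix_(indices, indices)] = block
    return token_seqs, ev_d


def _batch_course_distances(
    token_seqs: list[np.ndarray], ev_d: np.ndarray, chunk: int = 20_000
) -> np.ndarray:
    n = len(token_seqs)
    lens = np.array([len(t) for t in token_seqs], dtype=np.intp)
    lmax = int(lens.max(initial=0))
    padded = np.zeros((n, lmax), dtype=np.intp)
    for i, t in enumerate(token_seqs):
        padded[i, : len(t)] = t
    out = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    base = np.arange(lmax + 1, dtype=float)
    for start in range(0, len(iu), chunk):
        ii, jj = iu[start : start + chunk], ju[start : start + chunk]
        m = len(ii)
        a, b = padded[ii], padded[jj]
        dp = np.empty((m, lmax + 1, lmax + 1))
        dp[:, 0, :] = base
        dp[:, :, 0] = base
        for i in range(1, lmax + 1):
            cost = ev_d[a[:, i - 1][:, None], b]  # (m, lmax) substitution costs
            for j in range(1, lmax + 1):
                dp[:, i, j] = np.minimum(
                    np.minimum(dp[:, i - 1, j] + 1.0, dp[:, i, j - 1] + 1.0),
                    dp[:, i - 1, j - 1] + cost[:, j - 1],
                )
        la, lb = lens[ii], lens[jj]
        maxlen = np.maximum(np.maximum(la, lb), 1)
        raw = dp[np.arange(m), la, lb]
        out[ii, jj] = out[jj, ii] = raw / maxlen
    return out


def pairwise_matrix(
    courses: Sequence[TreatmentCourse],
    matrix: TherapyTypeMatrix | None = None,
    weights: AttributeWeights = DEFAULT_WEIGHTS,
) -> DistanceMatrix:
    """Symmetric course-distance matrix over a cohort.

    Each unordered pair is computed once; the result is deterministic for a
    fixed input order and independent of evaluation order.  Event-level
    distances are computed on a vocabulary of distinct events (dates play no
    role in event distance), which makes cohort-scale matrices tractable.
    """
    if len(courses) < 2:
        raise ValueError("pairwise_matrix needs at least two courses")
    ids = tuple(c.patient_id for c in courses)
    token_seqs, ev_d = _tokenize(courses, matrix, weights)
    values = _batch_course_distances(token_seqs, ev_d)
    return DistanceMatrix(ids, values)


# ---------------------------------------------------------------------------
# Medoids and neighbours
# ---------------------------------------------------------------------------


def medoid(member_ids: Iterable[str], matrix: DistanceMatrix) -> str:
    """The member minimising the summed distance to all other members;
    ties break towards the smallest id."""
    members = sorted(member_ids)
    if not members:
        raise ValueError("medoid of an empty membership is undefined")
    idx = [matrix.index_of(pid) for pid in members]
    sub = matrix.values[np.ix_(idx, idx)]
    sums = sub.sum(axis=1)
    return members[int(np.argmin(sums))]  # argmin returns the first (smallest id) on ties


def nearest_and_farthest(
    medoid_id: str,
    member_ids: Iterable[str],
    matrix: DistanceMatrix,
    k: int = 5,
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """The k most similar and k most dissimilar members relative to the
    medoid (medoid excluded), as (id, distance) pairs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mi = matrix.index_of(medoid_id)
    others = sorted(pid for pid in member_ids if pid != medoid_id)
    dists = [(pid, float(matrix.values[mi, matrix.index_of(pid)])) for pid in others]
    by_near = sorted(dists, key=lambda t: (t[1], t[0]))
    by_far = sorted(dists, key=lambda t: (-t[1], t[0]))
    return by_near[:k], by_far[:k]
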