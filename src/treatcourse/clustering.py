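"""Embedding, clustering model selection, and cluster reporting.

The course-distance matrix is embedded into 2D with UMAP (metric
"precomputed"), then three clustering algorithms -- agglomerative
hierarchical clustering with complete linkage, DBSCAN, and HDBSCAN -- are
grid-searched on the embedding.  Within a granularity band (a range of
admissible cluster counts) the configuration with the highest silhouette
score wins, subject to an outlier cap of 5% of the data.  Outlier points
(label -1) are excluded from both the cluster count and the silhouette.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import DBSCAN, HDBSCAN
from sklearn.metrics import silhouette_score

from .registry import (
    DiagnosisEvent,
    Event,
    RadiotherapyEvent,
    SurgeryEvent,
    SystemicTherapyEvent,
    TreatmentCourse,
)
from .sequences import DistanceMatrix, medoid, nearest_and_farthest

__all__ = [
    "COARSE",
    "MEDIUM",
    "FINE",
    "SURVIVAL_BAND",
    "ClusterReport",
    "ClusteringResult",
    "Embedding",
    "EmbeddingConfig",
    "GranularityBand",
    "GridSearchResult",
    "default_grids",
    "embed",
    "export_views",
    "grid_search",
    "headline_token",
    "silhouette_of",
    "summarize_cluster",
]


@dataclass(frozen=True)
class GranularityBand:
    """Admissible range of cluster counts for one reporting granularity."""

    name: str
    min_clusters: int
    max_clusters: int

    def __post_init__(self) -> None:
        if not 1 <= self.min_clusters <= self.max_clusters:
            raise ValueError("invalid band bounds")

    def contains(self, k: int) -> bool:
        return self.min_clusters <= k <= self.max_clusters

    @classmethod
    def from_string(cls, spec: str) -> "GranularityBand":
        """Parse "coarse" / "medium" / "fine" or "custom:MIN-MAX"."""
        presets = {"coarse": COARSE, "medium": MEDIUM, "fine": FINE}
        if spec in presets:
            return presets[spec]
        if spec.startswith("custom:"):
            lo, _, hi = spec.removeprefix("custom:").partition("-")
            return cls("custom", int(lo), int(hi))
        raise ValueError(f"unknown band {spec!r}")


COARSE = GranularityBand("coarse", 1, 50)
MEDIUM = GranularityBand("medium", 51, 100)
FINE = GranularityBand("fine", 101, 200)
#: The intercluster-survival workflow restricts to 15-30 clusters.
SURVIVAL_BAND = GranularityBand("survival", 15, 30)


@dataclass(frozen=True)
class EmbeddingConfig:
    n_dimensions: int = 2
    n_neighbors: int = 25
    min_dist: float = 0.1
    metric: str = "precomputed"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_dimensions != 2:
            raise ValueError("only 2D embeddings are supported")


@dataclass(frozen=True, eq=False)
class Embedding:
    """2D UMAP coordinates together with the configuration that made them."""

    coords: np.ndarray
    config: EmbeddingConfig
    ids: tuple[str, ...]

    def to_csv(self, path: str | Path) -> None:
        header = "config=" + json.dumps(self.config.__dict__, sort_keys=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {header}\n")
            fh.write("id,x,y\n")
            for pid, (x, y) in zip(self.ids, self.coords):
                fh.write(f"{pid},{float(x)!r},{float(y)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Embedding":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            cfg = EmbeddingConfig(**json.loads(first.lstrip("# ").removeprefix("config=")))
            ids, rows = [], []
            fh.readline()  # column header
            for line in fh:
                pid, x, y = line.rstrip("\n").split(",")
                ids.append(pid)
                rows.append((float(x), float(y)))
        return cls(np.array(rows), cfg, tuple(ids))


def embed(matrix: DistanceMatrix, config: EmbeddingConfig = EmbeddingConfig()) -> Embedding:
    """UMAP-embed a precomputed course-distance matrix into 2D.

    Identical seed and platform give identical coordinates; across platforms
    UMAP output may vary slightly, so tests should not assert exact
    coordinates.
    """
    values = matrix.values
    if not np.allclose(values, values.T) or np.any(np.diag(values) != 0) or np.any(values < 0):
        raise ValueError("embedding requires a symmetric, zero-diagonal, non-negative matrix")
    import umap  # deferred: numba compilation makes this import heavy

    reducer = umap.UMAP(
        n_components=config.n_dimensions,
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        metric=config.metric,
        random_state=config.seed,
    )
    coords = np.asarray(reducer.fit_transform(values), dtype=float)
    return Embedding(coords, config, matrix.ids)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ClusteringResult:
    algorithm: str
    params: Mapping[str, float]
    labels: np.ndarray  # -1 marks outliers
    silhouette: float  # NaN when undefined (fewer than 2 clusters)
    n_clusters: int = field(init=False)
    outlier_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        ks = set(labels.tolist()) - {-1}
        object.__setattr__(self, "n_clusters", len(ks))
        object.__setattr__(self, "outlier_fraction", float(np.mean(labels == -1)))

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in sorted(Counter(self.labels.tolist()).items())}

    def param_key(self) -> tuple:
        return tuple(sorted(self.params.items()))


@dataclass(frozen=True)
class GridSearchResult:
    band: GranularityBand
    best: ClusteringResult | None
    leaderboard: tuple[ClusteringResult, ...]

    @property
    def band_unsatisfiable(self) -> bool:
        return self.best is None


def default_grids() -> dict[str, dict[str, Sequence]]:
    return {
        "hierarchical": {"distance_threshold": np.geomspace(0.1, 30.0, 25)},
        "dbscan": {"eps": np.linspace(0.05, 2.0, 20), "min_samples": (5, 7, 10, 15, 25)},
        "hdbscan": {"min_cluster_size": (10, 25, 50, 100, 200), "min_samples": (5, 10, 25)},
    }


def silhouette_of(points: np.ndarray, labels: np.ndarray) -> float:
    """Euclidean silhouette on the embedding, outliers (-1) excluded.

    NaN when fewer than two clusters remain (silhouette is undefined).
    """
    mask = labels != -1
    kept = labels[mask]
    if len(set(kept.tolist())) < 2 or len(kept) < 3:
        return math.nan
    return float(silhouette_score(points[mask], kept, metric="euclidean"))


def _sort_value(s: float) -> float:
    return -math.inf if math.isnan(s) else s


def grid_search(
    embedding: Embedding | np.ndarray,
    band: GranularityBand,
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
    outlier_cap: float = 0.05,
) -> GridSearchResult:
    """Silhouette-selected clustering of the 2D embedding within a band.

    Evaluates complete-linkage hierarchical clustering over a
    distance-threshold grid, DBSCAN over an (eps, min_samples) grid and
    HDBSCAN over a (min_cluster_size, min_samples) grid.  Only results whose
    cluster count lies in the band and whose outlier fraction is at most
    ``outlier_cap`` are admissible; the admissible result with the highest
    silhouette wins, ties broken lexicographically by (algorithm name,
    parameter tuple).  An empty admissible set yields a result flagged
    ``band_unsatisfiable`` rather than an exception.
    """
    points = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    grids = grids if grids is not None else default_grids()
    candidates: list[ClusteringResult] = []

    hier = grids.get("hierarchical")
    if hier:
        z = linkage(points, method="complete")
        for t in hier["distance_threshold"]:
            labels = fcluster(z, t=float(t), criterion="distance") - 1
            candidates.append(
                ClusteringResult(
                    "hierarchical",
                    {"distance_threshold": float(t)},
                    labels,
                    silhouette_of(points, labels),
                )
            )
    db = grids.get("dbscan")
    if db:
        for eps in db["eps"]:
            for ms in db["min_samples"]:
                labels = DBSCAN(eps=float(eps), min_samples=int(ms)).fit_predict(points)
                candidates.append(
                    ClusteringResult(
                        "dbscan",
                        {"eps": float(eps), "min_samples": int(ms)},
                        labels,
                        silhouette_of(points, labels),
                    )
                )
    hdb = grids.get("hdbscan")
    if hdb:
        for mcs in hdb["min_cluster_size"]:
            for ms in hdb["min_samples"]:
                if int(ms) > len(points) or int(mcs) > len(points):
                    continue
                labels = HDBSCAN(min_cluster_size=int(mcs), min_samples=int(ms)).fit_predict(points)
                candidates.append(
                    ClusteringResult(
                        "hdbscan",
                        {"min_cluster_size": int(mcs), "min_samples": int(ms)},
                        labels,
                        silhouette_of(points, labels),
                    )
                )

    admissible = [
        c for c in candidates if band.contains(c.n_clusters) and c.outlier_fraction <= outlier_cap
    ]
    admissible.sort(key=lambda c: (-_sort_value(c.silhouette), c.algorithm, c.param_key()))
    best = admissible[0] if admissible else None
    return GridSearchResult(band, best, tuple(admissible))


# ---------------------------------------------------------------------------
# Cluster reports
# ---------------------------------------------------------------------------

_ROMAN = {0: "0", 1: "I", 2: "II", 3: "III", 4: "IV"}


def headline_token(event: Event) -> str:
    """The highest-weighted attribute of an event, as a display token.

    Diagnoses show the UICC stage, surgeries the surgery group,
    radiotherapies the target region, systemic therapies the therapy type.
    Missing values render as "?", unrelated ones as "*".
    """

    def show(av, fmt=str) -> str:
        if av.is_present:
            return fmt(av.value)
        return "?" if av.state.name == "MISSING" else "*"

    if isinstance(event, DiagnosisEvent):
        return show(event.uicc_stage, lambda v: _ROMAN[v])
    if isinstance(event, SurgeryEvent):
        return show(event.surgery_group)
    if isinstance(event, RadiotherapyEvent):
        return show(event.target_region)
    if isinstance(event, SystemicTherapyEvent):
        return show(event.therapy_type)
    raise TypeError(f"unsupported event {event!r}")


_EVENT_KIND = {
    DiagnosisEvent: "diagnosis",
    SurgeryEvent: "surgery",
    RadiotherapyEvent: "radiotherapy",
    SystemicTherapyEvent: "systemic",
}


@dataclass(frozen=True)
class ClusterReport:
    cluster_id: int
    size: int
    medoid_id: str
    medoid_tokens: tuple[str, ...]
    nearest: tuple[tuple[str, float], ...]
    farthest: tuple[tuple[str, float], ...]
    attribute_frequencies: Mapping[str, Counter]


def summarize_cluster(
    result: ClusteringResult,
    cluster_id: int,
    courses: Sequence[TreatmentCourse],
    matrix: DistanceMatrix,
    k: int = 5,
) -> ClusterReport:
    """Characterise one cluster by its medoid course and neighbours.

    The medoid course is rendered as its headline-attribute token sequence;
    the five most similar and most dissimilar member courses (relative to
    the medoid) are listed, plus per-attribute frequency tables over the
    members' headline attributes.
    """
    labels = result.labels
    member_idx = [i for i, lab in enumerate(labels) if lab == cluster_id]
    if not member_idx:
        raise ValueError(f"cluster {cluster_id} not present in the clustering result")
    by_id = {c.patient_id: c for c in courses}
    member_ids = [courses[i].patient_id for i in member_idx]
    med = medoid(member_ids, matrix)
    near, far = nearest_and_farthest(med, member_ids, matrix, k=k)
    freqs: dict[str, Counter] = {}
    for pid in member_ids:
        for event in by_id[pid].events:
            key = _EVENT_KIND[type(event)]
            freqs.setdefault(key, Counter())[headline_token(event)] += 1
    return ClusterReport(
        cluster_id=cluster_id,
        size=len(member_ids),
        medoid_id=med,
        medoid_tokens=tuple(headline_token(e) for e in by_id[med].events),
        nearest=tuple(near),
        farthest=tuple(far),
        attribute_frequencies=freqs,
    )


# ---------------------------------------------------------------------------
# Visual exports
# ---------------------------------------------------------------------------

_TOKEN_COLORS = {
    "BCS": "#1f77b4",
    "Mastectomy": "#ff7f0e",
    "OtherBreast": "#8c564b",
    "Breast": "#2ca02c",
    "Thorax": "#98df8a",
    "CH": "#d62728",
    "HO": "#9467bd",
}


def _token_color(event: Event, token: str) -> str:
    if token in _TOKEN_COLORS:
        return _TOKEN_COLORS[token]
    if isinstance(event, DiagnosisEvent):
        return "#7f7f7f"
    if isinstance(event, SystemicTherapyEvent):
        return "#e377c2"
    return "#c7c7c7"


def export_views(
    embedding: Embedding,
    result: ClusteringResult,
    courses: Sequence[TreatmentCourse],
    matrix: DistanceMatrix,
    out_dir: str | Path,
) -> list[Path]:
    """Write a cluster-coloured scatter plot and per-cluster sequence
    diagrams (one row per course, one cell per event, coloured and labelled
    by the headline attribute) as deterministic SVG files."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    matplotlib.rcParams["svg.hashsalt"] = "treatcourse"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cluster_ids = sorted(set(result.labels.tolist()) - {-1})
    reports = {cid: summarize_cluster(result, cid, courses, matrix) for cid in cluster_ids}

    fig, ax = plt.subplots(figsize=(9, 7))
    cmap = plt.get_cmap("tab20")
    for i, cid in enumerate(cluster_ids):
        mask = result.labels == cid
        rep = reports[cid]
        ax.scatter(
            embedding.coords[mask, 0],
            embedding.coords[mask, 1],
            s=8,
            color=cmap(i % 20),
            label=f"{cid}: {', '.join(rep.medoid_tokens)} (n={rep.size})",
        )
    noise = result.labels == -1
    if noise.any():
        ax.scatter(embedding.coords[noise, 0], embedding.coords[noise, 1], s=8, color="#cccccc",
                   label="outliers")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=6, frameon=False)
    fig.tight_layout()
    scatter_path = out_dir / "scatter.svg"
    fig.savefig(scatter_path, format="svg", metadata={"Date": None})
    plt.close(fig)
    written.append(scatter_path)

    by_id = {c.patient_id: c for c in courses}
    for cid in cluster_ids:
        member_ids = [courses[i].patient_id for i, lab in enumerate(result.labels) if lab == cid]
        rows = [by_id[pid] for pid in member_ids]
        max_len = max((len(c) for c in rows), default=0)
        fig, ax = plt.subplots(figsize=(max(4, 0.9 * max_len), max(1.5, 0.22 * len(rows))))
        for y, course in enumerate(rows):
            for x, event in enumerate(course.events):
                token = headline_token(event)
                ax.barh(y, 0.92, left=x, height=0.8, color=_token_color(event, token))
                if len(rows) <= 60:
                    ax.text(x + 0.46, y, token, ha="center", va="center", fontsize=5)
        ax.set_ylim(-0.6, len(rows) - 0.4)
        ax.set_xlim(0, max(max_len, 1))
        ax.invert_yaxis()
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(f"cluster {cid} (n={len(rows)})", fontsize=8)
        fig.tight_layout()
        path = out_dir / f"cluster_{cid}_sequence.svg"
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)
        written.append(path)
    return written
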