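"""Embedding, silhouette-selected grid search, cluster reports, exports."""

import datetime as dt
import math

import numpy as np
import pytest

from treatcourse.clustering import (
    COARSE,
    FINE,
    MEDIUM,
    SURVIVAL_BAND,
    ClusteringResult,
    EmbeddingConfig,
    Embedding,
    GranularityBand,
    embed,
    export_views,
    grid_search,
    headline_token,
    silhouette_of,
    summarize_cluster,
)
from treatcourse.registry import (
    DiagnosisEvent,
    MISSING,
    Radiation,
    RadiotherapyEvent,
    SurgeryEvent,
    SystemicTherapyEvent,
    TreatmentCourse,
    age_band,
    present,
)
from treatcourse.sequences import DistanceMatrix, pairwise_matrix

D = dt.date(2019, 5, 1)


class TestBands:
    def test_presets(self):
        assert (COARSE.min_clusters, COARSE.max_clusters) == (1, 50)
        assert (MEDIUM.min_clusters, MEDIUM.max_clusters) == (51, 100)
        assert (FINE.min_clusters, FINE.max_clusters) == (101, 200)
        assert (SURVIVAL_BAND.min_clusters, SURVIVAL_BAND.max_clusters) == (15, 30)

    def test_disjoint_and_ordered(self):
        assert COARSE.max_clusters < MEDIUM.min_clusters < MEDIUM.max_clusters < FINE.min_clusters

    def test_from_string(self):
        assert GranularityBand.from_string("coarse") is COARSE
        band = GranularityBand.from_string("custom:15-30")
        assert (band.min_clusters, band.max_clusters) == (15, 30)
        with pytest.raises(ValueError):
            GranularityBand.from_string("extreme")


def _two_group_matrix(n=30):
    """Planted two-group distance matrix: tight within, far between."""
    rng = np.random.default_rng(0)
    half = n // 2
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < half) == (j < half)
            v[i, j] = v[j, i] = rng.uniform(0.0, 0.1) if same else rng.uniform(0.8, 1.0)
    return DistanceMatrix(tuple(f"p{i}" for i in range(n)), v), np.array([i >= half for i in range(n)])


class TestEmbed:
    def test_separates_planted_groups(self):
        matrix, groups = _two_group_matrix()
        emb = embed(matrix, EmbeddingConfig(n_neighbors=5))
        a, b = emb.coords[~groups], emb.coords[groups]
        within = max(np.linalg.norm(a - a.mean(0), axis=1).mean(),
                     np.linalg.norm(b - b.mean(0), axis=1).mean())
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        assert between > 3 * within

    def test_same_seed_reproduces_coordinates(self):
        matrix, _ = _two_group_matrix(20)
        cfg = EmbeddingConfig(n_neighbors=5, seed=7)
        e1 = embed(matrix, cfg)
        e2 = embed(matrix, cfg)
        assert np.array_equal(e1.coords, e2.coords)

    def test_rejects_invalid_matrix(self):
        bad = DistanceMatrix(("a", "b"), np.array([[0.0, 0.3], [0.3, 0.0]]))
        object.__setattr__(bad, "values", np.array([[0.0, 0.3], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            embed(bad)

    def test_config_round_trips_through_persisted_output(self, tmp_path):
        matrix, _ = _two_group_matrix(20)
        cfg = EmbeddingConfig(n_neighbors=5, min_dist=0.2, seed=3)
        emb = embed(matrix, cfg)
        path = tmp_path / "emb.csv"
        emb.to_csv(path)
        back = Embedding.from_csv(path)
        assert back.config == cfg
        assert back.ids == emb.ids
        assert np.allclose(back.coords, emb.coords)


def _blobs(n=200, k=4, spread=0.05, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [8, 2]])[:k]
    labels = rng.integers(0, k, size=n)
    return centers[labels] + rng.normal(scale=spread, size=(n, 2)), labels


class TestGridSearch:
    def test_recovers_two_planted_blobs(self):
        points, truth = _blobs(n=120, k=2)
        result = grid_search(points, COARSE)
        assert not result.band_unsatisfiable
        assert result.best.n_clusters == 2
        assert result.best.silhouette > 0.8

    def test_band_unsatisfiable_on_pigeonhole(self):
        points, _ = _blobs(n=50, k=2)
        result = grid_search(points, FINE)
        assert result.band_unsatisfiable
        assert result.best is None

    def test_leaderboard_sorted_and_admissible(self):
        points, _ = _blobs(n=150, k=3)
        result = grid_search(points, COARSE)
        sils = [c.silhouette for c in result.leaderboard]
        cleaned = [-(s if not math.isnan(s) else -math.inf) for s in sils]
        assert cleaned == sorted(cleaned)
        for c in result.leaderboard:
            assert COARSE.contains(c.n_clusters)
            assert c.outlier_fraction <= 0.05
        assert result.best is result.leaderboard[0]

    def test_outlier_fraction_counts_noise_labels(self):
        labels = np.array([0] * 90 + [-1] * 10)
        res = ClusteringResult("x", {}, labels, 0.5)
        assert res.n_clusters == 1
        assert res.outlier_fraction == pytest.approx(0.1)


def naive_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) textbook silhouette (outliers excluded), as an oracle."""
    mask = labels != -1
    pts, labs = points[mask], labels[mask]
    dists = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(len(pts)):
        own = labs == labs[i]
        n_own = own.sum()
        if n_own == 1:
            scores.append(0.0)
            continue
        a = dists[i][own].sum() / (n_own - 1)
        b = min(dists[i][labs == c].mean() for c in set(labs.tolist()) if c != labs[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def test_silhouette_matches_naive_oracle():
    points, labels = _blobs(n=300, k=4, spread=0.8, seed=3)
    labels = labels.copy()
    labels[:7] = -1  # noise points are excluded from the score
    assert silhouette_of(points, labels) == pytest.approx(naive_silhouette(points, labels), abs=1e-9)


def test_silhouette_undefined_for_single_cluster():
    points, _ = _blobs(n=50, k=1)
    assert math.isnan(silhouette_of(points, np.zeros(50, dtype=int)))


def _report_courses():
    diag = DiagnosisEvent(present(1), present(0), present(age_band(55)),
                          present("8500/3"), present(2), D)
    bcs = SurgeryEvent(("5-870.1",), present(0), present(frozenset()), D)
    rt = RadiotherapyEvent((Radiation("Percutaneous", "Breast"),), present("A"), D)
    ho = SystemicTherapyEvent(present("HO"), present("A"), D)
    courses = [
        TreatmentCourse.build("a", [diag, bcs, rt]),
        TreatmentCourse.build("b", [diag, bcs, rt]),
        TreatmentCourse.build("c", [diag, bcs, ho]),
        TreatmentCourse.build("d", [diag, bcs]),
    ]
    return courses


class TestSummarizeCluster:
    def test_headline_tokens(self):
        courses = _report_courses()
        assert [headline_token(e) for e in courses[0].events] == ["I", "BCS", "Breast"]
        assert headline_token(SystemicTherapyEvent(MISSING, present("A"), D)) == "?"

    def test_report_contents_match_hand_tallies(self):
        courses = _report_courses()
        matrix = pairwise_matrix(courses)
        labels = np.zeros(4, dtype=int)
        result = ClusteringResult("manual", {}, labels, float("nan"))
        report = summarize_cluster(result, 0, courses, matrix)
        assert report.size == 4
        # a and b are identical and share the minimal summed distance; the
        # tie breaks to the smaller id
        assert report.medoid_id == "a"
        assert report.medoid_tokens == ("I", "BCS", "Breast")
        assert report.attribute_frequencies["diagnosis"] == {"I": 4}
        assert report.attribute_frequencies["surgery"] == {"BCS": 4}
        assert report.attribute_frequencies["radiotherapy"] == {"Breast": 2}
        assert report.attribute_frequencies["systemic"] == {"HO": 1}
        assert len(report.nearest) == 3 and len(report.farthest) == 3

    def test_singleton_cluster(self):
        courses = _report_courses()
        matrix = pairwise_matrix(courses)
        labels = np.array([0, 1, 1, 1])
        result = ClusteringResult("manual", {}, labels, float("nan"))
        report = summarize_cluster(result, 0, courses, matrix)
        assert report.size == 1
        assert report.nearest == () and report.farthest == ()

    def test_unknown_cluster_id(self):
        courses = _report_courses()
        matrix = pairwise_matrix(courses)
        result = ClusteringResult("manual", {}, np.zeros(4, dtype=int), float("nan"))
        with pytest.raises(ValueError):
            summarize_cluster(result, 5, courses, matrix)


class TestExportViews:
    def test_structure_and_determinism(self, tmp_path):
        courses = _report_courses()
        matrix = pairwise_matrix(courses)
        emb = Embedding(np.array([[0, 0], [0.1, 0], [3, 3], [3.1, 3]]), EmbeddingConfig(), matrix.ids)
        result = ClusteringResult("manual", {}, np.array([0, 0, 1, 1]), 0.9)
        out1 = export_views(emb, result, courses, matrix, tmp_path / "run1")
        names = sorted(p.name for p in out1)
        assert names == ["cluster_0_sequence.svg", "cluster_1_sequence.svg", "scatter.svg"]
        out2 = export_views(emb, result, courses, matrix, tmp_path / "run2")
        for p1, p2 in zip(sorted(out1), sorted(out2)):
            assert p1.read_bytes() == p2.read_bytes()
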