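"""Landmark survival workflow: filters, KM, Cox PH, G-computation."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from treatcourse.registry import Covariates, DiagnosisEvent, PatientRecord, TreatmentCourse
from treatcourse.simulate import default_breast_cohort, simulate_ph_clusters
from treatcourse.survival import (
    CohortFilterSpec,
    SurvivalRecord,
    build_subcohort,
    cox_fit,
    g_computation_curves,
    landmark_km,
    make_survival_records,
    select_reference_cluster,
)

from conftest import km_product_limit

DIAG = dt.date(2019, 3, 1)


def _record(pid="p", age=60, grading=2, uicc=1, death_days=None, substage="IA"):
    course = TreatmentCourse.build(pid, [DiagnosisEvent(date=DIAG)])
    return PatientRecord(
        patient_id=pid,
        course=course,
        diagnosis_date=DIAG,
        death_date=DIAG + dt.timedelta(days=death_days) if death_days else None,
        covariates=Covariates(age=age, grading=grading, uicc_stage=uicc,
                              uicc_substage=substage, histology_code="8500/3"),
    )


class TestBuildSubcohort:
    def test_filters_and_attrition(self):
        records = [
            _record("young", age=45),
            _record("early_death", death_days=30),
            _record("no_grading", grading=None),
            _record("wrong_stage", uicc=3),
            _record("keeper", age=55, uicc=2, substage="IIA"),
        ]
        kept, attrition = build_subcohort(records, CohortFilterSpec("PF"))
        assert [r.patient_id for r in kept] == ["keeper"]
        assert attrition == {"age_band": 1, "min_survival": 1, "grading_missing": 1,
                             "uicc_subgroup": 1}
        assert sum(attrition.values()) == len(records) - len(kept)

    def test_pu_takes_stages_three_and_four(self):
        records = [_record("iii", uicc=3, substage="IIIA"), _record("i", uicc=1)]
        kept, _ = build_subcohort(records, CohortFilterSpec("PU"))
        assert [r.patient_id for r in kept] == ["iii"]

    def test_landmark_survivor_at_exactly_56_days_kept(self):
        kept, _ = build_subcohort([_record(death_days=56)], CohortFilterSpec("PF"))
        assert len(kept) == 1


class TestMakeSurvivalRecords:
    def test_landmark_origin_and_censoring(self):
        rec = _record("p", death_days=100)
        (sr,) = make_survival_records([rec], {"p": 0})
        assert sr.time == 100 - 56
        assert sr.event
        alive = _record("q")
        (sr2,) = make_survival_records([alive], {"q": 1})
        assert not sr2.event
        assert sr2.time == (dt.date(2023, 6, 30) - (DIAG + dt.timedelta(days=56))).days

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("x", 0.0, True, 0, 60, 2, "IA", False)


def _sr(pid, time, event, cluster=0, **kw):
    base = dict(age=60.0, grading=2, uicc_substage="IIA", lobular=False)
    base.update(kw)
    return SurvivalRecord(pid, float(time), bool(event), cluster, base["age"],
                          base["grading"], base["uicc_substage"], base["lobular"])


class TestLandmarkKM:
    def test_hand_product_limit_example(self):
        records = [_sr("a", 100, 1), _sr("b", 300, 1), _sr("c", 500, 0), _sr("d", 1500, 0)]
        km = landmark_km(records)
        assert km.estimates[0].survival == pytest.approx(0.5)

    def test_all_die_immediately(self):
        records = [_sr(p, 1, 1) for p in "abc"]
        km = landmark_km(records)
        assert km.estimates[0].survival == 0.0

    def test_zero_death_cluster_excluded_with_reason(self):
        records = [_sr("a", 100, 1, 0), _sr("b", 900, 0, 1), _sr("c", 900, 0, 1)]
        km = landmark_km(records)
        assert 1 in km.excluded and "no deaths" in km.excluded[1]
        assert 1 not in km.estimates

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            landmark_km([])

    def test_matches_oracle_on_all_small_datasets(self):
        """Exhaustive product-limit check on every event pattern of up to
        six patients (with tied and untied event times)."""
        time_sets = [(30, 200, 400, 800, 1200, 1600), (100, 100, 300, 300, 500, 2000)]
        for times in time_sets:
            for n in range(1, 7):
                for flags in itertools.product((0, 1), repeat=n):
                    if not any(flags):
                        continue  # zero-death clusters are excluded, not estimated
                    records = [_sr(f"p{i}", times[i], flags[i]) for i in range(n)]
                    km = landmark_km(records)
                    expected = km_product_limit(times[:n], flags, 1460)
                    assert km.estimates[0].survival == pytest.approx(expected, abs=1e-12)


class TestReferenceCluster:
    def test_argmax_survival(self):
        records = [_sr("a", 100, 1, 0)] + [_sr(f"b{i}", 1500, i == 0, 1) for i in range(10)]
        km = landmark_km(records)
        assert select_reference_cluster(km) == 1

    def test_tie_breaks_by_size_then_label(self):
        # two clusters, each with one early death among different sizes
        small = [_sr("s0", 10, 1, 3)] + [_sr(f"s{i}", 2000, 0, 3) for i in range(1, 10)]
        large = [_sr("l0", 10, 1, 1)] + [_sr(f"l{i}", 2000, 0, 1) for i in range(1, 20)]
        km = landmark_km(small + large)
        assert km.estimates[3].survival == pytest.approx(0.9)
        assert km.estimates[1].survival == pytest.approx(0.95)
        assert select_reference_cluster(km) == 1

    def test_all_excluded_is_an_error(self):
        records = [_sr("a", 100, 0, 0)]
        km = landmark_km(records)
        with pytest.raises(ValueError):
            select_reference_cluster(km)


class TestCoxFit:
    def test_recovers_planted_binary_hazard_ratio(self):
        df = simulate_ph_clusters(2000, (0.0, np.log(2.0)), censoring_fraction=0.0, seed=10)
        records = [
            _sr(str(i), max(t, 1e-9), e, int(c))
            for i, (t, e, c) in enumerate(zip(df.time, df.event, df.cluster))
        ]
        fit = cox_fit(records, reference_cluster=0)
        assert 1.7 <= fit.hazard_ratio(1) <= 2.3

    def test_reference_rows_marked_with_unit_hazard(self):
        df = simulate_ph_clusters(300, (0.0, 0.5), seed=2)
        records = [
            _sr(str(i), max(t, 1e-9), e, int(c), grading=1 + i % 3, lobular=bool(i % 2))
            for i, (t, e, c) in enumerate(zip(df.time, df.event, df.cluster))
        ]
        fit = cox_fit(records, reference_cluster=0)
        table = fit.table
        ref = table[table.reference]
        assert (ref.hazard_ratio == 1.0).all()
        assert ref.ci_lower.isna().all()
        assert "Cluster 0 (reference)" in ref.term.values
        assert "Grading G1 (reference)" in ref.term.values

    def test_null_covariates_give_unit_hazard_ratios(self):
        rng = np.random.default_rng(3)
        records = [
            _sr(str(i), rng.exponential(10.0), True, int(i % 2))
            for i in range(400)
        ]
        fit = cox_fit(records, reference_cluster=0)
        assert fit.hazard_ratio(1) == pytest.approx(1.0, abs=0.25)


class TestGComputation:
    def _fit(self, n=400, log_hrs=(0.0, 0.5), seed=4):
        df = simulate_ph_clusters(n, log_hrs, seed=seed)
        rng = np.random.default_rng(seed)
        records = [
            _sr(str(i), max(t, 1e-9), e, int(c), age=float(rng.integers(50, 70)),
                grading=int(rng.integers(1, 4)), lobular=bool(rng.random() < 0.2))
            for i, (t, e, c) in enumerate(zip(df.time, df.event, df.cluster))
        ]
        return cox_fit(records, reference_cluster=0)

    def test_zero_cluster_coefficients_collapse_all_curves(self):
        fit = self._fit()
        for name in fit.model.params_.index:
            if name.startswith("cluster["):
                fit.model.params_[name] = 0.0
        curves = g_computation_curves(fit)
        assert np.max(np.abs(curves["cluster_0"] - curves["cluster_1"])) < 1e-9

    def test_null_model_reproduces_kaplan_meier(self):
        """A saturated-to-null model (all coefficients zero) must reproduce
        the pooled product-limit curve exactly."""
        fit = self._fit(n=120, log_hrs=(0.0, 0.0), seed=6)
        fit.model.params_[:] = 0.0
        curves = g_computation_curves(fit)
        times = np.array([r.time for r in fit.records])
        events = [bool(r.event) for r in fit.records]
        for t, s in zip(curves["time"], curves["cluster_0"]):
            assert s == pytest.approx(km_product_limit(times, events, t), abs=1e-6)

    def test_planted_ordering_and_shape(self):
        fit = self._fit(n=1200, log_hrs=(0.0, np.log(3.0)), seed=8)
        curves = g_computation_curves(fit)
        c0, c1 = curves["cluster_0"].to_numpy(), curves["cluster_1"].to_numpy()
        assert c0[0] == 1.0 and c1[0] == 1.0
        assert np.all(np.diff(c0) <= 1e-12) and np.all(np.diff(c1) <= 1e-12)
        assert np.all(c1[1:] <= c0[1:] + 1e-12)

    def test_time_grid_truncated_at_follow_up(self):
        fit = self._fit(n=100, seed=9)
        t_max = max(r.time for r in fit.records)
        curves = g_computation_curves(fit, time_grid=[0.0, t_max / 2, t_max * 10])
        assert curves["time"].max() <= t_max


def test_end_to_end_on_synthetic_cohort():
    """PF subcohort of a generated cohort, clustered by planted archetype."""
    records, truth = default_breast_cohort(4000, seed=11)
    kept, attrition = build_subcohort(records, CohortFilterSpec("PF"))
    assert sum(attrition.values()) + len(kept) == len(records)
    assert len(kept) > 100
    arch_codes = {a: i for i, a in enumerate(sorted(truth.archetype.unique()))}
    labels = dict(zip(truth.patient_id, truth.archetype.map(arch_codes)))
    srecs = make_survival_records(kept, labels)
    km = landmark_km(srecs)
    assert km.estimates  # at least one cluster with deaths
    ref = select_reference_cluster(km)
    fit = cox_fit(srecs, ref, exclude_clusters=km.excluded.keys())
    assert fit.hazard_ratio(ref) == 1.0
    curves = g_computation_curves(fit)
    assert set(curves.columns) == {"time"} | {f"cluster_{c}" for c in fit.cluster_levels}
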