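"""Product-limit estimator and log-rank test against oracles and lifelines."""

import numpy as np
import pytest

from oamlseq.cohort_stats import build_matrix
from oamlseq.io_formats import PatientRecord
from oamlseq.survival import (
    KMEstimate,
    SurvivalRecord,
    dfs_by_mutation,
    km_estimate,
    logrank_test,
    write_km_table,
)
from oamlseq.annotation import AnnotatedMutation, ConsequenceClass
from oamlseq.io_formats import VariantCall


def _records(times, events, group="g"):
    return [
        SurvivalRecord(f"{group}{i}", t, bool(e), group)
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKaplanMeier:
    def test_hand_computed_three_patient_example(self):
        # event at 2, censored at 1, event at 3
        est = km_estimate(_records([2, 1, 3], [1, 0, 1]))
        assert est.survival_at(2) == pytest.approx(0.5)
        assert est.survival_at(3) == pytest.approx(0.0)
        assert est.survival_at(1.5) == 1.0  # before the first event

    def test_no_events_flat_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            est = km_estimate(_records([5, 10], [0, 0]))
        assert est.survival_at(100) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 40).round(3)
        est = km_estimate(_records(times, np.ones(40)))
        for t in np.linspace(0.1, times.max(), 25):
            assert est.survival_at(t) == pytest.approx((times > t).mean())

    def test_distinct_event_times_step_by_one_over_n(self):
        est = km_estimate(_records([1, 2, 3, 4], [1, 1, 1, 1]))
        assert est.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_greenwood_zero_before_first_event(self):
        est = km_estimate(_records([5, 8], [1, 1]))
        assert est.survival_at(1) == 1.0
        assert est.greenwood_se[0] > 0

    def test_ties_events_before_censorings(self):
        # censoring at t=2 keeps the subject at risk for the t=2 event
        est = km_estimate(_records([2, 2, 4], [1, 0, 1]))
        assert est.survival_at(2) == pytest.approx(2 / 3)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(9)
        times = rng.exponential(12, 80).round(2)
        events = rng.random(80) < 0.7
        est = km_estimate(_records(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        for t in est.event_times:
            assert est.survival_at(t) == \
                pytest.approx(float(kmf.predict(t)), abs=1e-9)

    def test_requires_records(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        a = _records([3, 5, 8, 13], [1, 1, 0, 1], "A")
        b = _records([3, 5, 8, 13], [1, 1, 0, 1], "B")
        stat, p = logrank_test(a, b)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(4)
        a = _records(rng.exponential(10, 30), rng.random(30) < 0.8, "A")
        b = _records(rng.exponential(5, 30), rng.random(30) < 0.8, "B")
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(8)
        ta = rng.exponential(10, 25)
        tb = rng.exponential(4, 25)
        a = _records(ta, np.ones(25), "A")
        b = _records(tb, np.ones(25), "B")
        a2 = _records(np.sqrt(ta), np.ones(25), "A")
        b2 = _records(np.sqrt(tb), np.ones(25), "B")
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(a2, b2)[0])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(10, 40), rng.exponential(5, 40)
        ea, eb = rng.random(40) < 0.8, rng.random(40) < 0.8
        stat, p = logrank_test(_records(ta, ea, "A"), _records(tb, eb, "B"))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_zero_variance_warns_p_one(self):
        a = _records([5.0], [1], "A")
        b = _records([1.0], [0], "B")
        # the only event happens when group B is no longer at risk
        with pytest.warns(UserWarning, match="variance"):
            stat, p = logrank_test(a, b)
        assert p == 1.0


class TestDfsByMutation:
    @staticmethod
    def _clinical(n, times, relapse):
        return [
            PatientRecord(f"P{i}", 60, "M", "I", "orbita", "radiotherapy",
                          bool(relapse[i]), False, float(times[i]), 0.8)
            for i in range(n)
        ]

    @staticmethod
    def _mut(pid, gene="MYD88"):
        return AnnotatedMutation(
            variant=VariantCall(pid, "chr3", 38182641, "T", "C", gene,
                                150, 60, 35.0),
            verdict="accept",
            consequence=ConsequenceClass("substitution", "missense"),
        )

    def test_groups_and_logrank_output(self):
        n = 10
        clinical = self._clinical(n, [10 + i for i in range(n)],
                                  [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        muts = [self._mut("P0"), self._mut("P1"), self._mut("P2")]
        matrix = build_matrix(muts, [p.patient_id for p in clinical])
        res = dfs_by_mutation(matrix, clinical, "MYD88")
        assert res["n_mutated"] == 3 and res["n_wildtype"] == 7
        assert "logrank_p" in res

    def test_gene_with_no_mutations_single_group(self):
        clinical = self._clinical(4, [10, 20, 30, 40], [1, 0, 0, 0])
        matrix = build_matrix([], [p.patient_id for p in clinical])
        res = dfs_by_mutation(matrix, clinical, "FAS")
        assert res["n_mutated"] == 0
        assert "logrank_p" not in res
        assert "km_wildtype" in res

    def test_missing_clinical_patients_dropped_and_reported(self):
        clinical = self._clinical(3, [10, 20, 30], [1, 0, 0])
        matrix = build_matrix([], [p.patient_id for p in clinical] + ["PX"])
        res = dfs_by_mutation(matrix, clinical, "MYD88")
        assert res["dropped_patients"] == ["PX"]

    def test_unknown_gene_is_error(self):
        clinical = self._clinical(2, [10, 20], [1, 0])
        matrix = build_matrix([], [p.patient_id for p in clinical])
        with pytest.raises(ValueError, match="not in panel"):
            dfs_by_mutation(matrix, clinical, "NOSUCH")

    def test_stage_subset_as_pre_filter(self):
        clinical = self._clinical(6, [10, 20, 30, 40, 50, 60],
                                  [1, 1, 0, 0, 0, 0])
        clinical[5].ann_arbor_stage = "II"
        muts = [self._mut("P0"), self._mut("P5")]
        matrix = build_matrix(muts, [p.patient_id for p in clinical])
        stage1 = [p for p in clinical if p.ann_arbor_stage == "I"]
        res = dfs_by_mutation(matrix, stage1, "MYD88")
        assert res["n_mutated"] == 1  # P5 excluded by the stage filter
        assert "P5" in res["dropped_patients"]

    def test_doubled_hazard_shortens_mutated_median(self):
        """Simulation oracle: with the mutated group's hazard doubled the
        mutated KM median falls below the wild-type median almost surely."""
        rng = np.random.default_rng(17)
        wins = 0
        n_sims, n = 200, 200
        for _ in range(n_sims):
            mutated = rng.random(n) < 0.5
            rate = np.where(mutated, 0.04, 0.02)
            t = rng.exponential(1.0 / rate)
            censor = rng.uniform(50, 400, n)
            obs = np.minimum(t, censor)
            event = t <= censor
            clinical = self._clinical(n, np.maximum(obs, 0.01), event)
            muts = [self._mut(f"P{i}") for i in range(n) if mutated[i]]
            matrix = build_matrix(muts, [p.patient_id for p in clinical])
            res = dfs_by_mutation(matrix, clinical, "MYD88")
            m_med = res["km_mutated"].median
            w_med = res["km_wildtype"].median
            wins += (not np.isnan(m_med) and not np.isnan(w_med)
                     and m_med < w_med)
        assert wins / n_sims >= 0.95


def test_km_table_writer(tmp_path):
    est = km_estimate(_records([2, 1, 3], [1, 0, 1]))
    path = tmp_path / "km.tsv"
    write_km_table([est], path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 3  # header + two event times
    assert lines[1].split("\t")[4] == "0.5"
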