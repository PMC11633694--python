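"""Change scores, gated tests, worked-example arithmetic, LMM and pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import omtrial as ot
from omtrial.datamodel import ParameterError, SmallSampleError
from omtrial.metrics import LongOutcomeTable
from omtrial.stats import normality_gate
from omtrial.synthetic import DEFAULT_INSTRUMENTS, InstrumentSpec


class TestWaldSummary:
    @pytest.mark.parametrize(
        "coef,se,t2,p2",
        [
            (10033.0, 3183.7, 3.15, 0.002),
            (-4696.3, 2013.5, -2.33, 0.02),
            (-60.70, 48.3, -1.26, 0.21),
        ],
    )
    def test_printed_coefficient_tables_reproduce(self, coef, se, t2, p2):
        t, p = ot.wald_summary(coef, se)
        assert round(t, 2) == t2
        assert round(p, len(str(p2).split(".")[1])) == p2

    def test_null_point(self):
        t, p = ot.wald_summary(0.0, 3.0)
        assert t == 0.0 and p == 1.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ParameterError):
            ot.wald_summary(1.0, 0.0)


class TestPooledMean:
    def test_subgroup_age_and_mmse_pool_to_totals(self):
        age, age_sd = ot.pooled_mean([70.3, 67.2], [3, 5], [6.0, 11.2])
        assert round(age, 1) == 68.4 and round(age_sd, 1) == 9.2
        mmse, mmse_sd = ot.pooled_mean([15.3, 19.2], [3, 5], [3.2, 4.8])
        assert round(mmse, 1) == 17.7 and round(mmse_sd, 1) == 4.5

    def test_equal_means_pool_to_themselves(self):
        assert ot.pooled_mean([5.0, 5.0], [2, 9]) == pytest.approx(5.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            ot.pooled_mean([1.0], [1, 2])


class TestPlannedRecruitment:
    @pytest.mark.parametrize("n,rate,planned", [(24, 0.20, 30), (24, 0.0, 24), (10, 0.5, 20)])
    def test_attrition_inflation(self, n, rate, planned):
        assert ot.planned_recruitment(n, rate).planned_n == planned

    def test_full_attrition_rejected(self):
        with pytest.raises(ParameterError):
            ot.planned_recruitment(24, 1.0)


class TestMultiplicity:
    def test_bonferroni_arithmetic(self):
        adj, sig = ot.adjust_multiplicity([0.002] + [0.5] * 11)
        assert adj[0] == pytest.approx(0.024) and sig[0]
        adj, sig = ot.adjust_multiplicity([0.02] + [0.5] * 11)
        assert adj[0] == pytest.approx(0.24) and not sig[0]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_holm_never_exceeds_bonferroni(self, ps):
        bonf, _ = ot.adjust_multiplicity(ps, method="bonferroni")
        holm, _ = ot.adjust_multiplicity(ps, method="holm")
        assert np.all(holm <= bonf + 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            ot.adjust_multiplicity([])


class TestChangeScores:
    @staticmethod
    def records(sid, scores):
        return [ot.QuestionnaireRecord(sid, "NPI", "caregiver", w, s)
                for w, s in zip(ot.WEEKS, scores)]

    def test_end_of_arm_minus_baseline(self):
        recs = self.records("S01", [20.0, 23.0, 21.0, 19.0])
        changes, excl = ot.change_scores(recs, [ot.Assignment("S01", ot.LEV_FIRST)])
        assert excl == []
        by_session = {c.session: c for c in changes}
        assert by_session[1].delta == pytest.approx(3.0)
        assert by_session[1].arm_drug == 1
        assert by_session[2].delta == pytest.approx(-2.0)
        assert by_session[2].arm_drug == 0

    def test_flat_scores_give_zero_deltas(self):
        recs = self.records("S01", [10.0] * 4)
        changes, _ = ot.change_scores(recs, [ot.Assignment("S01", ot.PBO_FIRST)])
        assert all(c.delta == 0.0 for c in changes)

    def test_missing_week_listed_not_dropped_silently(self):
        recs = self.records("S01", [20.0, 23.0, 21.0, 19.0])[:3]  # week 20 missing
        changes, excl = ot.change_scores(recs, [ot.Assignment("S01", ot.LEV_FIRST)])
        assert len(changes) == 1
        assert any("missing week 20" in e for e in excl)

    def test_injected_drug_effect_recovered_from_deltas(self):
        # +2 points on NPI while on drug: mean(active) - mean(placebo) deltas ~ 2
        instruments = tuple(
            InstrumentSpec(s.instrument, s.respondent, s.mean, s.between_sd,
                           s.noise_sd, drug_effect=2.0 if s.instrument == "NPI" else 0.0)
            for s in DEFAULT_INSTRUMENTS
        )
        diffs = []
        for seed in range(10):
            cfg = ot.CohortConfig(
                n_subjects=400, allocation={ot.LEV_FIRST: 200, ot.PBO_FIRST: 200},
                instruments=instruments, seed=seed,
            )
            data = ot.generate_cohort(cfg, include_trials=False)
            changes, _ = ot.change_scores(
                data.dataset.questionnaires, data.dataset.assignments
            )
            npi = [c for c in changes if c.instrument == "NPI"]
            active = np.mean([c.delta for c in npi if c.arm_drug == 1])
            placebo = np.mean([c.delta for c in npi if c.arm_drug == 0])
            diffs.append(active - placebo)
        assert np.mean(diffs) == pytest.approx(2.0, abs=0.3)


class TestNormalityGate:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        gate = normality_gate(rng.normal(0, 1, 200))
        assert gate.normal and gate.p_value >= 0.05

    def test_heavy_tails_fail(self):
        rng = np.random.default_rng(1)
        gate = normality_gate(rng.standard_t(1, size=50))
        assert not gate.normal

    def test_constant_differences_flagged(self):
        gate = normality_gate([2.0, 2.0, 2.0, 2.0])
        assert not gate.normal and "constant" in gate.note

    def test_too_small_rejected(self):
        with pytest.raises(SmallSampleError):
            normality_gate([1.0, 2.0])


class TestPairedComparison:
    def test_identical_arms_are_null(self):
        res = ot.compare_change_between_arms([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == 1.0 and "degenerate" in res.note

    def test_large_shift_detected(self):
        rng = np.random.default_rng(2)
        placebo = rng.normal(0, 1, 8)
        active = placebo + 5 + rng.normal(0, 1, 8)
        res = ot.compare_change_between_arms(active, placebo)
        assert res.p_value < 0.01
        if res.method == "paired_t":
            assert res.ci_low > 0

    def test_branch_is_pure_function_of_gate(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 30)
        b = a + rng.normal(0.1, 1, 30)
        res = ot.compare_change_between_arms(b, a)
        gate = normality_gate(np.asarray(b) - np.asarray(a))
        assert res.method == ("paired_t" if gate.normal else "wilcoxon_signed_rank")
        assert res.normality_p == gate.p_value
        # deterministic on a fixed dataset
        res2 = ot.compare_change_between_arms(b, a)
        assert (res.method, res.statistic, res.p_value) == (
            res2.method, res2.statistic, res2.p_value
        )

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ParameterError):
            ot.compare_change_between_arms([1.0, 2.0, 3.0], [1.0, 2.0])


class TestBaselineComparison:
    def test_equal_count_table_is_null(self):
        res = ot.compare_baseline_groups(np.array([[5, 5], [7, 7]]), categorical=True)
        assert res.method == "chi_square" and res.p_value == 1.0

    def test_sex_split_not_significant(self):
        # M/F 0/3 vs 3/2 across sequence groups
        table = np.array([[0, 3], [3, 2]])
        res = ot.compare_baseline_groups(table, categorical=True)
        assert res.statistic == pytest.approx(2.88, abs=0.01)
        assert res.p_value > 0.05

    def test_continuous_comparison_runs_both_branches(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.2, 1, 30)])
        labels = ["a"] * 30 + ["b"] * 30
        res = ot.compare_baseline_groups(values, labels)
        assert res.method in ("two_sample_t", "mann_whitney_u")
        heavy = np.concatenate([rng.standard_t(1, 30), rng.standard_t(1, 30)])
        res2 = ot.compare_baseline_groups(heavy, labels)
        assert res2.method == "mann_whitney_u"

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            ot.compare_baseline_groups([1.0, 2.0], ["a", "a"])


class TestAdverseEvents:
    def test_arm_totals_and_grand_total(self):
        recs = [
            ot.AdverseEventRecord("S01", "placebo", "headache", 11),
            ot.AdverseEventRecord("S01", "active", "headache", 9),
            ot.AdverseEventRecord("S02", "placebo", "fatigue", 8),
            ot.AdverseEventRecord("S02", "active", "fatigue", 7),
        ]
        s = ot.adverse_event_summary(recs, subjects=["S01", "S02", "S03"])
        assert s.arm_totals == {"placebo": 19, "active": 16}
        assert s.grand_total == 35
        assert s.term_totals["headache"] == 20
        # roster subject with no reports contributes zero counts to both arms
        row = s.per_subject.set_index("subject_id").loc["S03"]
        assert row["active"] == 0 and row["placebo"] == 0

    def test_identical_counts_are_null(self):
        recs = [
            ot.AdverseEventRecord("S01", "placebo", "headache", 2),
            ot.AdverseEventRecord("S01", "active", "nausea", 2),
            ot.AdverseEventRecord("S02", "placebo", "fatigue", 1),
            ot.AdverseEventRecord("S02", "active", "fatigue", 1),
        ]
        s = ot.adverse_event_summary(recs)
        assert s.test.statistic == 0.0 and s.test.p_value == 1.0


class TestRandomInterceptLMM:
    @staticmethod
    def table_from(frame):
        return LongOutcomeTable(outcome_name="identification_time", frame=frame)

    def make_long(self, n_subj=12, m=10, beta=(100.0, 0.0, 50.0, -20.0),
                  tau=5.0, sigma=10.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_subj):
            u = rng.normal(0, tau)
            seq = i % 2
            for s in (1, 2):
                d = seq if s == 1 else 1 - seq
                for j in range(m):
                    y = (beta[0] + beta[1] * s + beta[2] * d + beta[3] * s * d
                         + u + rng.normal(0, sigma))
                    rows.append((f"S{i:02d}", s, d, 8 if s == 1 else 20, j, y))
        return self.table_from(pd.DataFrame(
            rows, columns=["subject_id", "session", "drug", "week", "trial_index", "value"]
        ))

    def test_t_equals_coef_over_se_as_stored(self):
        res = ot.fit_random_intercept_lmm(self.make_long())
        for term in res.terms.values():
            assert term.t_value == pytest.approx(
                term.coefficient / term.standard_error, abs=1e-9
            )

    def test_recovers_known_coefficients(self):
        res = ot.fit_random_intercept_lmm(self.make_long(n_subj=60, m=40, seed=1))
        assert res.terms["drug"].coefficient == pytest.approx(50.0, abs=6.0)
        assert res.terms["session_x_drug"].coefficient == pytest.approx(-20.0, abs=4.0)
        assert res.sigma2_residual == pytest.approx(100.0, rel=0.15)
        assert res.sigma2_subject == pytest.approx(25.0, rel=0.6)

    def test_zero_subject_variance_flagged_not_raised(self):
        res = ot.fit_random_intercept_lmm(self.make_long(tau=0.0, seed=2))
        assert res.sigma2_subject < 1.0
        assert isinstance(res.converged, bool)

    def test_needs_two_subjects_and_sessions(self):
        frame = self.make_long().frame
        with pytest.raises(SmallSampleError):
            ot.fit_random_intercept_lmm(self.table_from(frame[frame.subject_id == "S00"]))
        with pytest.raises(SmallSampleError):
            ot.fit_random_intercept_lmm(self.table_from(frame[frame.session == 1]))

    def test_df_method_options_agree_on_t(self):
        table = self.make_long(seed=3)
        for method in ("normal", "satterthwaite", "cr2", 6):
            res = ot.fit_random_intercept_lmm(table, df_method=method)
            drug = res.terms["drug"]
            assert 0.0 <= drug.p_value <= 1.0
            assert drug.t_value == pytest.approx(drug.coefficient / drug.standard_error)


class TestPipeline:
    def test_report_structure(self, cohort):
        report = ot.analyze_trial(cohort.dataset)
        assert set(report.lmm) == set(
            ("proportion_correct", "absolute_error", "identification_time",
             "localization_time")
        )
        assert len(report.multiplicity) == 12  # 4 outcomes x 3 non-intercept terms
        for res in report.questionnaire_tests.values():
            assert 0.0 <= res.p_value <= 1.0
        assert report.ae_summary.grand_total == sum(
            r.n_instances for r in cohort.dataset.adverse_events
        )
        assert set(report.baseline_tests) == {"age", "baseline_mmse", "sex"}

    def test_mixture_fits_included_on_request(self, cohort):
        report = ot.analyze_trial(cohort.dataset, fit_mixtures=True,
                                  outcomes=("absolute_error",))
        assert report.mixture_fits is not None
        assert {"p_target", "p_misbind", "sigma_px"} <= set(report.mixture_fits.columns)
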