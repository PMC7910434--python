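import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import micropoint as mp
from helpers import build_exam, naive_cohort_stats, naive_eye_summary, random_exam


class TestCriterion:
    def test_unrounded_cutoffs_are_exact_products(self):
        assert mp.CRITERION_5PCT.cutoff_db == pytest.approx(2.937)
        assert mp.CRITERION_2_5PCT.cutoff_db == pytest.approx(3.56)

    def test_rounded_cutoffs_match_clinical_convention(self):
        assert mp.AbnormalityCriterion(1.65, rounded=True).cutoff_db == 2.9
        assert mp.AbnormalityCriterion(2.0, rounded=True).cutoff_db == 3.6

    def test_strict_inequality_at_cutoff(self):
        crit = mp.CRITERION_5PCT
        assert not crit.is_abnormal(-crit.cutoff_db)
        assert crit.is_abnormal(-crit.cutoff_db - 1e-9)

    def test_intermediate_deviation_separates_criteria(self):
        # -3.50 dB: beyond 1.65 SD (2.937) but not 2 SD (3.56)
        assert mp.CRITERION_5PCT.is_abnormal(-3.50)
        assert not mp.CRITERION_2_5PCT.is_abnormal(-3.50)


class TestScoreExam:
    def test_calibrated_control_mean_scores_normal(self, model, criteria):
        """The printed control mean plus the 2.67 dB adjustment sits on
        the age-expected value: deviation ~0, normal under both criteria."""
        exam = build_exam(25.9, age=62.2)
        scores = mp.score_exam(exam, model, mp.CalibrationOffset(2.67), criteria)
        for s in scores:
            assert s.deviation == pytest.approx(0.0, abs=0.01)
            assert not any(s.abnormal.values())

    def test_zero_offset_identity(self, model, criteria):
        expected = mp.expected_threshold(model, 62.2)
        exam = build_exam(expected, age=62.2)
        scores = mp.score_exam(exam, model, mp.NO_OFFSET, criteria)
        assert all(s.deviation == pytest.approx(0.0, abs=1e-12) for s in scores)
        assert all(s.adjusted_threshold == pytest.approx(expected) for s in scores)

    def test_nested_criteria(self, model, criteria, small_dataset):
        for exam in small_dataset.exams:
            for s in mp.score_exam(exam, model, mp.CalibrationOffset(2.67), criteria):
                if s.abnormal["z2"]:
                    assert s.abnormal["z1.65"]

    def test_requires_criteria(self, model, make_exam):
        with pytest.raises(ValueError, match="criterion"):
            mp.score_exam(make_exam(25.0), model, mp.NO_OFFSET, [])


def _scores_with_deviations(model, deviations, *, age=62.2, criteria=None):
    criteria = criteria or mp.default_criteria()
    expected = mp.expected_threshold(model, age)
    exam = build_exam(np.asarray(deviations) + expected, age=age)
    return mp.score_exam(exam, model, mp.NO_OFFSET, criteria)


class TestSummarizeEye:
    def test_constant_depressed_grid(self, model):
        scores = _scores_with_deviations(model, np.full(33, -5.0))
        out = mp.summarize_eye(scores, mp.CRITERION_5PCT)
        assert out.n_abnormal == 33
        assert out.mean_deviation_abnormal == pytest.approx(-5.0)
        assert out.within_grid_sd == pytest.approx(0.0)
        assert out.frac_abnormal == 1.0

    def test_mixed_grid_hand_example(self, model):
        deviations = np.concatenate([np.full(10, -4.0), np.zeros(23)])
        out = mp.summarize_eye(
            _scores_with_deviations(model, deviations), mp.CRITERION_5PCT
        )
        assert out.n_abnormal == 10
        assert out.mean_deviation_abnormal == pytest.approx(-4.0)
        assert out.mean_deviation_all == pytest.approx(-40.0 / 33)

    def test_no_abnormal_points_flagged_undefined(self, model):
        out = mp.summarize_eye(
            _scores_with_deviations(model, np.zeros(33)), mp.CRITERION_5PCT
        )
        assert not out.has_abnormal
        assert math.isnan(out.mean_deviation_abnormal)
        assert math.isnan(out.mean_threshold_abnormal)
        assert out.n_abnormal == 0

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mp.summarize_eye([], mp.CRITERION_5PCT)

    def test_abnormal_mean_below_cutoff_whenever_defined(
        self, model, criteria, small_dataset
    ):
        offset = mp.CalibrationOffset(2.67)
        for exam in small_dataset.exams:
            scores = mp.score_exam(exam, model, offset, criteria)
            for criterion in criteria:
                out = mp.summarize_eye(scores, criterion, exam=exam)
                if out.has_abnormal:
                    assert out.mean_deviation_abnormal <= -criterion.cutoff_db

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_on_random_exams(self, model, seed):
        rng = np.random.default_rng(seed)
        exam = random_exam(rng)
        for criterion in mp.default_criteria():
            scores = mp.score_exam(exam, model, mp.CalibrationOffset(2.67), [criterion])
            out = mp.summarize_eye(scores, criterion, exam=exam)
            naive = naive_eye_summary(scores, criterion)
            for key, value in naive.items():
                got = getattr(out, key)
                if isinstance(value, float) and math.isnan(value):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(value, abs=1e-9), key


class TestMonotonicity:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_n_abnormal_decreases_with_z(self, model, seed):
        rng = np.random.default_rng(seed)
        exam = random_exam(rng)
        criteria = mp.default_criteria()
        scores = mp.score_exam(exam, model, mp.NO_OFFSET, criteria)
        n165 = mp.summarize_eye(scores, criteria[0]).n_abnormal
        n200 = mp.summarize_eye(scores, criteria[1]).n_abnormal
        assert n200 <= n165

    @given(
        seed=st.integers(0, 2**31 - 1),
        lo=st.floats(-1, 3, allow_nan=False),
        delta=st.floats(0, 3, allow_nan=False),
    )
    @settings(max_examples=30, deadline=None)
    def test_larger_offset_never_adds_abnormal_points(self, model, seed, lo, delta):
        rng = np.random.default_rng(seed)
        exam = random_exam(rng)
        criterion = mp.CRITERION_5PCT
        n_lo = mp.summarize_eye(
            mp.score_exam(exam, model, mp.CalibrationOffset(lo), [criterion]),
            criterion,
        ).n_abnormal
        n_hi = mp.summarize_eye(
            mp.score_exam(exam, model, mp.CalibrationOffset(lo + delta), [criterion]),
            criterion,
        ).n_abnormal
        assert n_hi <= n_lo


class TestEligibility:
    def _outcomes(self, model, counts):
        outs = []
        for i, n_abn in enumerate(counts):
            deviations = np.concatenate(
                [np.full(n_abn, -6.0), np.zeros(33 - n_abn)]
            )
            scores = _scores_with_deviations(model, deviations)
            out = mp.summarize_eye(scores, mp.CRITERION_5PCT)
            outs.append(
                out.__class__(**{**vars(out), "exam_index": i + 1})
            )
        return outs

    def test_both_exams_qualify(self, model):
        assert mp.check_eligibility(self._outcomes(model, [5, 5]), 5, True)

    def test_no_abnormal_never_eligible(self, model):
        outs = self._outcomes(model, [0, 0])
        assert not mp.check_eligibility(outs, 5, True)
        assert not mp.check_eligibility(outs, 5, False)

    def test_any_versus_all_rule(self, model):
        outs = self._outcomes(model, [6, 3])
        assert not mp.check_eligibility(outs, 5, True)
        assert mp.check_eligibility(outs, 5, False)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            mp.check_eligibility([], 5, True)


class TestSummarizeCohort:
    def _toy_outcomes(self, model, counts, exam_index=1):
        outs = []
        for i, n_abn in enumerate(counts):
            deviations = np.concatenate(
                [np.full(n_abn, -6.0), np.zeros(33 - n_abn)]
            )
            exam = build_exam(
                np.asarray(deviations) + mp.expected_threshold(model, 62.2),
                subject_id=f"S{i:03d}",
                exam_index=exam_index,
            )
            scores = mp.score_exam(exam, model, mp.NO_OFFSET, [mp.CRITERION_5PCT])
            outs.append(mp.summarize_eye(scores, mp.CRITERION_5PCT, exam=exam))
        return outs

    def test_four_eye_toy_cohort(self, model):
        outs = self._toy_outcomes(model, [0, 2, 6, 12])
        summary = mp.summarize_cohort(outs, min_abnormal=5)
        row = summary.per_exam.iloc[0]
        assert row["n_eyes"] == 4
        assert row["n_abnormal_mean"] == pytest.approx(5.0)
        assert row["n_excluded_no_abnormal"] == 1
        # abnormal-restricted aggregates over the 3 eyes with >= 1 point
        assert row["mean_deviation_abnormal_mean"] == pytest.approx(-6.0)
        elig = summary.eligibility.set_index("rule")
        assert elig.loc["exam_1", "pct_eligible"] == pytest.approx(50.0)
        assert elig.loc["exam_1", "n_eligible"] == 2

    def test_identical_eyes_collapse_spread(self, model):
        outs = self._toy_outcomes(model, [7, 7, 7])
        row = mp.summarize_cohort(outs).per_exam.iloc[0]
        assert row["n_abnormal_sd"] == pytest.approx(0.0)
        assert row["n_abnormal_min"] == row["n_abnormal_max"] == 7

    def test_both_percent_conventions_reported(self, model):
        outs = self._toy_outcomes(model, [0, 33])
        row = mp.summarize_cohort(outs).per_exam.iloc[0]
        assert row["pct_abnormal_pooled"] == pytest.approx(50.0)
        assert row["pct_abnormal_mean_of_eyes"] == pytest.approx(50.0)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_oracle_equivalence_on_random_cohorts(self, model, seed):
        rng = np.random.default_rng(seed)
        outs = []
        for i in range(6):
            exam = random_exam(rng, subject_id=f"S{i:03d}")
            scores = mp.score_exam(
                exam, model, mp.CalibrationOffset(2.67), [mp.CRITERION_5PCT]
            )
            outs.append(mp.summarize_eye(scores, mp.CRITERION_5PCT, exam=exam))
        row = mp.summarize_cohort(outs, min_abnormal=5).per_exam.iloc[0]
        naive = naive_cohort_stats(outs)
        for key, value in naive.items():
            if isinstance(value, float) and math.isnan(value):
                assert math.isnan(row[key])
            else:
                assert row[key] == pytest.approx(value, abs=1e-9), key

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            mp.summarize_cohort([])
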