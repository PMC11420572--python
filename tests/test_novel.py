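"""Menu survival, menu abundancy, enriched loyalty and PE recency."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import engagekit as ek
from engagekit.errors import InsufficientDataError, ValidationError

from conftest import make_activity, pe_oracle

W90 = ek.StudyWindow(0, 90)


class TestMenuSurvival:
    @pytest.mark.parametrize(
        "days,expected",
        [
            ([0, 10, 20], 20.0),        # 70-day trailing gap => stop at day 20
            ([5], 0.0),                 # single use, immediate discontinuation
            ([0, 30, 60], 60.0),        # 30-day cadence, never a 45-day gap
            ([], 0.0),                  # never used
            ([0, 10, 60, 70], 10.0),    # 50-day mid-gap cuts survival at day 10
            ([0, 44, 88], 88.0),        # gaps just under the threshold
        ],
    )
    def test_45_day_rule(self, days, expected):
        assert ek.menu_survival(days, W90) == expected

    def test_out_of_window_uses_ignored(self):
        assert ek.menu_survival([95, 100], W90) == 0.0
        assert ek.menu_survival([80, 95], W90) == 0.0

    def test_threshold_is_configurable(self):
        assert ek.menu_survival([0, 30, 60], W90, gap_threshold_days=30) == 0.0

    def test_cohort_table_shape(self, study_cohort):
        log, _ = study_cohort
        surv = ek.menu_survival_cohort(
            log, ek.StudyWindow(90, 180), ek.COMBINATIONS["EI2"]
        )
        assert list(surv.columns) == list(ek.COMBINATIONS["EI2"].menus)
        assert len(surv) == 233
        assert (surv.to_numpy() >= 0).all()
        assert (surv.to_numpy() <= 90).all()


class TestMenuAbundancy:
    def worked_example(self):
        return pd.DataFrame(
            {"m1": [0.0, 30.0, 60.0], "m2": [0.0, 40.0, 80.0]},
            index=["p1", "p2", "p3"],
        )

    def test_worked_example_and_endpoints(self):
        mi = ek.menu_abundancy(self.worked_example())
        assert mi["p1"] == 0.0       # the minimum-norm patient
        assert mi["p3"] == 1.0       # the maximum-norm patient
        assert mi["p2"] == pytest.approx(0.5)

    def test_translation_invariance(self):
        base = self.worked_example()
        shifted = base + np.array([7.0, 13.0])
        assert np.allclose(
            ek.menu_abundancy(base), ek.menu_abundancy(shifted), atol=1e-12
        )

    def test_scale_invariance(self):
        base = self.worked_example()
        assert np.allclose(
            ek.menu_abundancy(base), ek.menu_abundancy(base * 3.7), atol=1e-12
        )

    def test_identical_cohort_warns_and_returns_zero(self):
        flat = pd.DataFrame({"m1": [5.0, 5.0], "m2": [1.0, 1.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="identical"):
            mi = ek.menu_abundancy(flat)
        assert (mi == 0.0).all()

    def test_orthogonal_outlier_clipped_to_one(self):
        # p sits far from v_min orthogonally: raw ratio > 1, clipped
        surv = pd.DataFrame(
            {"m1": [4.0, 5.0, 0.0], "m2": [0.0, 0.0, 4.5]}, index=["lo", "hi", "p"]
        )
        with pytest.warns(UserWarning, match="clipped"):
            mi = ek.menu_abundancy(surv)
        assert mi["p"] == 1.0

    def test_norm_ties_broken_by_patient_id(self):
        surv = pd.DataFrame(
            {"m1": [3.0, 0.0, 5.0], "m2": [0.0, 3.0, 5.0]}, index=["b", "a", "c"]
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mi = ek.menu_abundancy(surv)
        assert mi["a"] == 0.0  # 'a' precedes 'b' among the tied minimum norms


class TestNewLoyalty:
    def test_raw_value_and_cohort_rescale(self):
        acts = {
            "a": make_activity(range(1, 11), {}, 13, visit_days=[7 * w for w in range(10)]),
            "b": make_activity([1], {}, 13),
        }
        # give patient a a final usage week of 12
        acts["a"] = make_activity(list(range(1, 11)) + [12], {}, 13)
        li = ek.new_loyalty(acts)
        raw_a = (11 + math.log(12)) / 13
        raw_b = 1 / 13
        assert li["a"] == 1.0
        assert li["b"] == pytest.approx(raw_b / raw_a)

    def test_log_term_zero_at_final_week_one(self):
        acts = {"a": make_activity([1], {}, 13), "b": make_activity([1, 2], {}, 13)}
        li = ek.new_loyalty(acts)
        # raw_a = 1/13 (ln 1 = 0); raw_b = (2 + ln 2)/13
        assert li["a"] == pytest.approx((1 / 13) / ((2 + math.log(2)) / 13))

    def test_all_zero_cohort(self):
        acts = {"a": make_activity([], {}, 13), "b": make_activity([], {}, 13)}
        assert (ek.new_loyalty(acts) == 0.0).all()


class TestPermutationEntropy:
    def test_monotone_series_has_zero_entropy(self):
        for m in (2, 3, 4):
            assert ek.permutation_entropy(range(10), order=m) == 0.0

    def test_two_pattern_hand_example(self):
        # (4,7,9,10,6,11,3): 4 ascents, 2 descents among 6 pairs
        expected = -(4 / 6 * math.log(4 / 6) + 2 / 6 * math.log(2 / 6)) / math.log(2)
        pe = ek.permutation_entropy([4, 7, 9, 10, 6, 11, 3], order=2)
        assert pe == pytest.approx(expected, abs=1e-12)

    def test_iid_noise_approaches_one(self):
        rng = np.random.default_rng(42)
        pe = ek.permutation_entropy(rng.standard_normal(20000), order=3)
        assert pe > 0.999

    def test_ties_ranked_by_position(self):
        # constant series: one pattern with probability 1
        assert ek.permutation_entropy([3, 3, 3, 3, 3], order=3) == 0.0

    def test_exhaustive_oracle_equivalence_small(self):
        for m in (2, 3):
            for length in range(m, 9):
                for seq in itertools.product((0, 1, 2), repeat=length):
                    assert ek.permutation_entropy(seq, order=m) == pytest.approx(
                        pe_oracle(seq, m), abs=1e-12
                    )

    @settings(max_examples=200, deadline=None)
    @given(
        seq=st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=12),
        m=st.sampled_from([2, 3]),
        tau=st.sampled_from([1, 2]),
    )
    def test_oracle_equivalence_property(self, seq, m, tau):
        if len(seq) < (m - 1) * tau + 1:
            return
        pe = ek.permutation_entropy(seq, order=m, delay=tau)
        assert 0.0 <= pe <= 1.0
        assert pe == pytest.approx(pe_oracle(seq, m, tau), abs=1e-12)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            ek.permutation_entropy([1, 2], order=3)
        with pytest.raises(ValidationError):
            ek.permutation_entropy([1, 2, 3], order=1)


class TestNewRecency:
    def test_constant_weekly_counts_score_one(self):
        acts = {
            "a": make_activity(
                range(1, 14), {}, 13,
                visit_days=[7 * w + d for w in range(13) for d in (0, 2, 4)],
            ),
            "b": make_activity([1, 5], {}, 13, visit_days=[0, 1, 30]),
        }
        ri = ek.new_recency(acts)
        assert ri["a"] == pytest.approx(1.0)

    def test_irregular_counts_score_low(self):
        rng = np.random.default_rng(3)
        acts = {}
        for i in range(20):
            counts = rng.integers(0, 6, size=52)
            days = [7 * w + d for w, c in enumerate(counts) for d in range(c)]
            acts[f"p{i}"] = make_activity(
                sorted({d // 7 + 1 for d in days}), {}, 52, visit_days=days
            )
        ri = ek.new_recency(acts)
        assert ri.mean() < 0.25

    def test_short_series_flagged_to_zero(self):
        acts = {"a": make_activity([1], {}, 2, visit_days=[0])}
        ri = ek.new_recency(acts, order=3)
        assert ri["a"] == 0.0

    def test_truncated_normal_calibration_preserves_order_and_range(self):
        rng = np.random.default_rng(5)
        acts = {}
        for i in range(30):
            counts = rng.integers(0, 4, size=26)
            days = [7 * w + d for w, c in enumerate(counts) for d in range(c)]
            acts[f"p{i}"] = make_activity(
                sorted({d // 7 + 1 for d in days}), {}, 26, visit_days=days
            )
        plain = ek.new_recency(acts, calibration="none")
        calibrated = ek.new_recency(acts, calibration="truncated_normal_cdf")
        assert ((calibrated >= 0) & (calibrated <= 1)).all()
        # 1 - CDF is monotone decreasing in PE, so the patient ranking is preserved
        assert (plain.rank() - calibrated.rank()).abs().max() == 0

    def test_unknown_calibration_rejected(self):
        with pytest.raises(ValidationError):
            ek.new_recency({}, calibration="quantile")


class TestNewEICohort:
    def test_ei_is_exact_mean_and_labelled(self, study_cohort):
        log, _ = study_cohort
        frame = ek.new_ei_cohort(log, ek.StudyWindow(90, 180), combination="EI2")
        mean = frame[["mi", "li", "ri"]].mean(axis=1)
        assert np.array_equal(frame["ei"].to_numpy(), mean.to_numpy())
        assert (frame["combination_label"] == "EI2").all()
        for col in ("mi", "li", "ri", "ei"):
            assert frame[col].between(0, 1).all()

    def test_cohort_max_loyalty_is_one(self, study_cohort):
        log, _ = study_cohort
        frame = ek.new_ei_cohort(log, ek.StudyWindow(90, 180), combination="EI3")
        assert frame["li"].max() == pytest.approx(1.0)
        assert frame["mi"].max() == pytest.approx(1.0)

    def test_zero_activity_guard(self):
        events = [ek.UsageEvent("active", "meal_log", 91 + 7 * w) for w in range(12)]
        log = ek.UsageLog(events, 540, patient_ids=["active", "ghost"])
        frame = ek.new_ei_cohort(log, ek.StudyWindow(90, 180), combination="EI3")
        assert frame.loc["ghost", ["mi", "li", "ri", "ei"]].tolist() == [0, 0, 0, 0]

    def test_unknown_combination_rejected(self, study_cohort):
        log, _ = study_cohort
        with pytest.raises(ValidationError, match="EI9"):
            ek.new_ei_cohort(log, ek.StudyWindow(90, 180), combination="EI9")

    def test_determinism(self, study_cohort):
        log, _ = study_cohort
        w = ek.StudyWindow(90, 180)
        a = ek.new_ei_cohort(log, w, combination="EI1")
        b = ek.new_ei_cohort(log, w, combination="EI1")
        assert a.equals(b)


def test_combination_definitions():
    assert set(ek.COMBINATIONS["EI1"].menus) == {
        "meal_log", "exercise_log", "message_sent", "reading_content", "weight_log"
    }
    assert set(ek.COMBINATIONS["EI2"].menus) == {
        "meal_log", "exercise_log", "weight_log", "step_count"
    }
    assert set(ek.COMBINATIONS["EI3"].menus) == set(ek.MENUS)


def test_nonusage_gap_percentile(study_cohort):
    log, _ = study_cohort
    q75 = ek.nonusage_gap_percentile(log, 75)
    assert q75 >= 1.0
    assert q75 <= ek.nonusage_gap_percentile(log, 95)
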