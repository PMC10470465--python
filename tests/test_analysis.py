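"""Trial filtering, summaries, LMM-ANOVA, correlations, head statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hyperrigid import (
    angles_from_pose,
    confidence_rt_correlation,
    filter_trials,
    head_movement_stats,
    lmm_anova,
    summarize,
)
from hyperrigid.analysis import DegenerateDesignError


def toy_log(n=10, n_timeout=2, n_wrong=2, subject="S1"):
    correct = [True] * (n - n_timeout - n_wrong) + [False] * n_wrong
    df = pd.DataFrame(
        {
            "subject": subject,
            "dimension": 3,
            "displacement_axis": "x",
            "irregularity": 0.12,
            "correct": correct + [False] * n_timeout,
            "rt_ms": [500.0] * (n - n_timeout) + [None] * n_timeout,
            "confidence": [4] * (n - n_timeout) + [None] * n_timeout,
            "timed_out": [False] * (n - n_timeout) + [True] * n_timeout,
        }
    )
    return df


class TestFiltering:
    def test_timed_out_trials_dropped(self):
        res = filter_trials(toy_log(10, n_timeout=2), exclude_subjects=False)
        assert len(res.trials) == 8
        assert res.report["n_timed_out_dropped"] == 2

    def test_rt_view_keeps_correct_trials_only(self):
        res = filter_trials(toy_log(10, n_timeout=2, n_wrong=2),
                            exclude_subjects=False)
        assert len(res.rt_view) == 6
        assert res.rt_view["correct"].all()

    def test_chance_level_low_confidence_subject_excluded(self):
        """A 54.9%-accuracy, confidence-1.71 subject over 108 trials is dropped."""
        rng = np.random.default_rng(0)
        n, k = 108, round(0.549 * 108)
        guesser = pd.DataFrame(
            {
                "subject": "ZZ",
                "dimension": 3,
                "displacement_axis": "x",
                "irregularity": 0.12,
                "correct": [True] * k + [False] * (n - k),
                "rt_ms": rng.uniform(400, 2000, n),
                "confidence": np.round(np.clip(rng.normal(1.71, 0.5, n), 1, 5)),
                "timed_out": False,
            }
        )
        good = toy_log(108, n_timeout=0, n_wrong=10, subject="S1")
        res = filter_trials(pd.concat([guesser, good], ignore_index=True))
        assert res.excluded_subjects == ("ZZ",)
        assert set(res.trials["subject"]) == {"S1"}

    def test_confident_chance_subject_retained(self):
        """At-chance accuracy alone does not exclude if confidence is high."""
        df = toy_log(108, n_timeout=0, n_wrong=54)  # 50% but confidence 4
        res = filter_trials(df)
        assert res.excluded_subjects == ()

    def test_training_sessions_dropped_by_default(self):
        df = toy_log(10, n_timeout=0)
        df["training"] = [True] * 4 + [False] * 6
        res = filter_trials(df, exclude_subjects=False)
        assert len(res.trials) == 6
        assert res.report["n_training_dropped"] == 4

    def test_filtering_is_idempotent_and_reconciles(self):
        df = toy_log(20, n_timeout=3, n_wrong=5)
        first = filter_trials(df, exclude_subjects=False)
        second = filter_trials(first.trials, exclude_subjects=False)
        pd.testing.assert_frame_equal(first.trials, second.trials)
        r = first.report
        assert r["n_input"] == r["n_retained"] + r["n_timed_out_dropped"] + \
            r["n_training_dropped"] + r["n_subject_excluded_dropped"]

    def test_malformed_log_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            filter_trials(pd.DataFrame({"subject": ["S1"]}))


class TestSummarize:
    def test_all_correct_cell_is_100_with_zero_sd(self):
        df = toy_log(6, n_timeout=0, n_wrong=0)
        table = summarize(df)
        row = table.loc[(3, "x")]
        assert row["accuracy_mean"] == 100.0
        assert row["accuracy_sd"] == 0.0

    def test_half_correct_cell_sd_from_indicator(self):
        """One correct + one incorrect trial: accuracy 50, SD of {0, 100}."""
        df = toy_log(2, n_timeout=0, n_wrong=1)
        row = summarize(df).loc[(3, "x")]
        assert row["accuracy_mean"] == 50.0
        assert row["accuracy_sd"] == pytest.approx(np.std([0, 100], ddof=1))

    def test_rt_summary_uses_correct_trials_only(self):
        df = toy_log(4, n_timeout=0, n_wrong=2)
        df.loc[~df["correct"], "rt_ms"] = 2900.0
        row = summarize(df).loc[(3, "x")]
        assert row["rt_mean"] == 500.0

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            summarize(toy_log(0, 0, 0).iloc[:0])


def _two_level_data(effect=0.0, n_per_cell=100, n_subjects=4, subject_sd=0.0,
                    seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        off = rng.normal(0, subject_sd)
        for lev, mu in (("A", 0.0), ("B", effect)):
            y = rng.normal(mu + off, 1.0, n_per_cell)
            rows.append(pd.DataFrame({"subject": f"S{s}", "factor": lev, "y": y}))
    return pd.concat(rows, ignore_index=True)


class TestLmmAnova:
    def test_matches_one_way_anova_without_subject_variance(self):
        """Zero between-subject variance, large n: F within 1% of one-way ANOVA."""
        df = _two_level_data(effect=0.3, n_per_cell=250, subject_sd=0.0, seed=1)
        res = lmm_anova(df, "y", ["factor"], "subject")
        f_ref = stats.f_oneway(
            df.loc[df["factor"] == "A", "y"], df.loc[df["factor"] == "B", "y"]
        ).statistic
        assert res.f("factor") == pytest.approx(f_ref, rel=0.01)

    def test_detects_a_real_effect(self):
        df = _two_level_data(effect=1.0, n_per_cell=50, subject_sd=0.5, seed=2)
        res = lmm_anova(df, "y", ["factor"], "subject")
        assert res.p("factor") < 1e-6

    def test_interaction_term_reported(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(4):
            for a in ("x", "y", "z"):
                for d in (3, 4):
                    rows.append(pd.DataFrame({
                        "subject": f"S{s}", "axis": a, "dim": d,
                        "y": rng.normal(0, 1, 20),
                    }))
        df = pd.concat(rows, ignore_index=True)
        res = lmm_anova(df, "y", ["axis", "dim"], "subject")
        assert set(res.table.index) == {"axis", "dim", "axis:dim"}
        assert (res.table["df_num"] == [2, 1, 2]).all()
        assert res.metadata["ddf_method"].startswith("residual")

    def test_constant_response_flagged_degenerate(self):
        df = _two_level_data(effect=0.0, n_per_cell=10)
        df["y"] = 5.0
        res = lmm_anova(df, "y", ["factor"], "subject")
        assert res.metadata["degenerate"]
        assert (res.table["F"] == 0.0).all()

    def test_single_subject_rejected(self):
        df = _two_level_data(n_subjects=1)
        with pytest.raises(DegenerateDesignError):
            lmm_anova(df, "y", ["factor"], "subject")

    def test_aggregate_mode_runs_on_cell_means(self):
        df = _two_level_data(effect=0.5, n_per_cell=40, n_subjects=6,
                             subject_sd=0.3, seed=4)
        res = lmm_anova(df, "y", ["factor"], "subject", aggregate=True)
        assert res.metadata["n_obs"] == 12  # 6 subjects x 2 levels
        assert res.metadata["aggregate"]

    def test_identical_input_identical_output(self):
        df = _two_level_data(effect=0.2, subject_sd=0.4, seed=5)
        a = lmm_anova(df, "y", ["factor"], "subject")
        b = lmm_anova(df, "y", ["factor"], "subject")
        pd.testing.assert_frame_equal(a.table, b.table)


class TestCorrelation:
    def test_perfect_negative_relation(self):
        df = pd.DataFrame({
            "confidence": [5, 4, 3, 2, 1],
            "rt_ms": [100.0, 200.0, 300.0, 400.0, 500.0],
        })
        r, p = confidence_rt_correlation(df)
        assert r == pytest.approx(-1.0)
        assert p < 0.01

    def test_shuffled_pairs_are_uncorrelated(self):
        rng = np.random.default_rng(6)
        n = 5000
        df = pd.DataFrame({
            "confidence": rng.integers(1, 6, n).astype(float),
            "rt_ms": rng.uniform(200, 2500, n),
        })
        r, _ = confidence_rt_correlation(df)
        assert abs(r) < 0.05

    def test_zero_variance_undefined(self):
        df = pd.DataFrame({"confidence": [3, 3, 3], "rt_ms": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            confidence_rt_correlation(df)

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"confidence": [1, 2], "rt_ms": [1.0, 2.0]})
        with pytest.raises(ValueError):
            confidence_rt_correlation(df)


class TestHeadStats:
    def test_constant_trace_has_zero_range(self):
        df = pd.DataFrame({
            "trial": 0, "angle_x": 5.0, "angle_y": 45.0, "angle_z": 1.0,
        }, index=range(54))
        out = head_movement_stats(df)
        assert out.loc[0, "median_y"] == 45.0
        assert (out.filter(like="range_") == 0).all().all()

    def test_quartile_rule_on_worked_example(self):
        """Samples {10,20,30,40}: median 25, Q3 - Q1 = 32.5 - 17.5 = 15."""
        df = pd.DataFrame({
            "trial": 0,
            "angle_x": [10.0, 20.0, 30.0, 40.0],
            "angle_y": 0.0, "angle_z": 0.0,
        })
        out = head_movement_stats(df)
        assert out.loc[0, "median_x"] == 25.0
        assert out.loc[0, "range_x"] == pytest.approx(15.0)

    def test_single_sample_trace_rejected(self):
        df = pd.DataFrame({"trial": [0], "angle_x": [1.0], "angle_y": [2.0],
                           "angle_z": [3.0]})
        with pytest.raises(ValueError):
            head_movement_stats(df)


class TestPoseAngles:
    def test_collinear_pose_gives_zero_angles(self):
        """Viewing direction aligned with the head-to-object vector -> 0 deg."""
        pos = np.array([[0.0, 0.0, 200.0]])
        view = np.array([[0.0, 0.0, -1.0]])
        ang = angles_from_pose(pos, view, np.zeros(3))
        assert np.allclose(ang, 0.0, atol=1e-9)

    def test_pure_yaw_appears_on_the_y_axis(self):
        pos = np.array([[0.0, 0.0, 200.0]])
        view = np.array([[np.sin(np.radians(30)), 0.0, -np.cos(np.radians(30))]])
        ang = angles_from_pose(pos, view, np.zeros(3))
        assert ang[0, 1] == pytest.approx(30.0, abs=1e-9) or \
            ang[0, 1] == pytest.approx(-30.0, abs=1e-9)
        assert ang[0, 0] == pytest.approx(0.0, abs=1e-9)
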