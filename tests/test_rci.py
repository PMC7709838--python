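import numpy as np
import pandas as pd
import pytest

from cogdecline import (
    ClassificationRule,
    ReliableChangeModel,
    classify_all,
    classify_subject_timepoint,
    flag_metric,
    make_schedule,
    summarize_timepoints,
    z_score,
    z_score_table,
)
from cogdecline.exceptions import ValidationError
from cogdecline.rci import round_half_up
from conftest import make_scores


def z_frame(records):
    """records: (subject, occasion, test, metric, z)"""
    return pd.DataFrame(records, columns=["subject_id", "occasion", "test_id", "metric", "z"])


class TestZScore:
    def test_delta_equal_to_learning_mean_centres_to_zero(self):
        assert z_score(-0.02, -0.02, 0.05) == 0.0

    def test_accuracy_example(self):
        # (-0.10 - (-0.02)) / 0.03
        assert z_score(-0.10, -0.02, 0.03) == pytest.approx(-2.667, abs=5e-4)

    def test_rt_example(self):
        # (0.25 - (-0.05)) / 0.10
        assert z_score(0.25, -0.05, 0.10) == pytest.approx(3.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValidationError):
            z_score(0.1, 0.0, 0.0)

    def test_table_requires_matching_learning_keys(self):
        changes = pd.DataFrame(
            [{"subject_id": "S1", "occasion": 2, "test_id": "ldt", "metric": "rt", "delta": 0.1}]
        )
        effects = pd.DataFrame(
            [{"test_id": "stroop", "metric": "rt", "mean_change": 0.0, "sd_change": 0.1,
              "n_control": 5}]
        )
        with pytest.raises(ValidationError, match="ldt"):
            z_score_table(changes, effects)


class TestFlagMetric:
    rule = ClassificationRule()

    def test_accuracy_flags_on_large_negative_z(self):
        assert flag_metric(-2.667, "accuracy", self.rule)
        assert not flag_metric(2.667, "accuracy", self.rule)

    def test_rt_flags_on_large_positive_z(self):
        assert flag_metric(2.1, "rt", self.rule)
        assert not flag_metric(-2.1, "rt", self.rule)

    def test_zero_never_flags_either_convention(self):
        for conv in ("internal", "paper"):
            r = ClassificationRule(sign_convention=conv)
            assert not flag_metric(0.0, "accuracy", r)
            assert not flag_metric(0.0, "rt", r)

    def test_boundary_is_strict(self):
        assert not flag_metric(1.96, "rt", self.rule)
        assert not flag_metric(-1.96, "accuracy", self.rule)
        assert flag_metric(np.nextafter(1.96, 2), "rt", self.rule)

    def test_paper_convention_swaps_inequalities(self):
        r = ClassificationRule(sign_convention="paper")
        assert flag_metric(2.5, "accuracy", r)
        assert flag_metric(-2.5, "rt", r)
        assert not flag_metric(-2.5, "accuracy", r)

    def test_convention_duality_on_negated_deltas(self):
        rng = np.random.default_rng(12)
        zs = rng.normal(0, 2, 200)
        internal = ClassificationRule(sign_convention="internal")
        paper = ClassificationRule(sign_convention="paper")
        for metric in ("accuracy", "rt"):
            a = [flag_metric(z, metric, internal) for z in zs]
            b = [flag_metric(-z, metric, paper) for z in zs]
            assert a == b


class TestClassifySubjectTimepoint:
    def test_single_flag_among_ten_triggers_decline(self):
        records = [("S1", 2, t, m, 0.0) for t in ("nback1", "nback2", "nback3", "stroop") for m in ("accuracy", "rt")]
        records += [("S1", 2, "ldt", "accuracy", 0.5), ("S1", 2, "ldt", "rt", 2.5)]
        c = classify_subject_timepoint(z_frame(records))
        assert c.decline
        assert c.triggers == (("ldt", "rt", 2.5),)

    def test_all_zero_scores_never_decline(self):
        records = [("S1", 3, t, m, 0.0) for t in ("nback1", "stroop") for m in ("accuracy", "rt")]
        for combine in ("any_test_metric", "composite_mean_z"):
            c = classify_subject_timepoint(z_frame(records), ClassificationRule(combine=combine))
            assert not c.decline

    def test_composite_uses_oriented_mean(self):
        # rt z = 1.0 on 5 tests, accuracy z = -1.0 on 5 tests -> oriented mean 1.0
        tests = ("nback1", "nback2", "nback3", "stroop", "ldt")
        records = [("S1", 2, t, "rt", 1.0) for t in tests]
        records += [("S1", 2, t, "accuracy", -1.0) for t in tests]
        c = classify_subject_timepoint(
            z_frame(records), ClassificationRule(combine="composite_mean_z")
        )
        assert c.composite_z == pytest.approx(1.0)
        assert not c.decline

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            classify_subject_timepoint(z_frame([]))

    def test_lowering_threshold_never_unflags(self):
        rng = np.random.default_rng(5)
        tests = ("nback1", "nback2", "stroop")
        records = [
            (f"S{i}", occ, t, m, rng.normal(0, 1.5))
            for i in range(20)
            for occ in (2, 3)
            for t in tests
            for m in ("accuracy", "rt")
        ]
        z = z_frame(records)
        flagged_prev: set = set()
        for threshold in (2.5, 2.0, 1.5, 1.0):
            cls = classify_all(z, ClassificationRule(z_threshold=threshold))
            flagged = set(
                map(tuple, cls[cls.decline][["subject_id", "occasion"]].to_numpy())
            )
            assert flagged_prev <= flagged
            flagged_prev = flagged


class TestSummarize:
    def _classifications(self, counts, n=15):
        rows = []
        for occ, k in counts.items():
            for i in range(n):
                rows.append(
                    {"subject_id": f"I{i:02d}", "occasion": occ, "decline": i < k,
                     "triggers": "", "composite_z": None}
                )
        return pd.DataFrame(rows)

    def test_printed_percentages_round_to_nearest_integer(self):
        counts = dict(zip(range(2, 10), [3, 4, 5, 4, 4, 6, 5, 6]))
        summary = summarize_timepoints(self._classifications(counts))
        pct = [round_half_up(p) for p in summary["pct_decline"]]
        assert pct == [20, 27, 33, 27, 27, 40, 33, 40]
        assert (summary["n_decline"] + summary["n_normal"] == summary["n_total"]).all()

    def test_forty_percent_case(self):
        summary = summarize_timepoints(self._classifications({2: 6}))
        assert summary["pct_decline"].iloc[0] == pytest.approx(40.0)

    def test_no_decline_gives_zero_percent(self):
        summary = summarize_timepoints(self._classifications({2: 0}, n=12))
        assert summary["pct_decline"].iloc[0] == 0.0

    def test_missing_cells_rejected(self):
        cls = self._classifications({2: 3, 3: 4})
        cls = cls.drop(cls[(cls.subject_id == "I03") & (cls.occasion == 3)].index)
        with pytest.raises(ValidationError):
            summarize_timepoints(cls)

    def test_schedule_labels_attached(self):
        summary = summarize_timepoints(self._classifications({7: 6}), make_schedule())
        assert "180" in summary["event_label"].iloc[0]


class TestModelInterface:
    def test_fit_produces_coherent_results(self):
        scores = make_scores(
            n_subjects=8,
            occasions=tuple(range(1, 10)),
            tests=("nback1", "stroop"),
            prefix="I",
            cohort="intervention",
            seed=21,
        )
        control = make_scores(n_subjects=5, seed=22)
        res = ReliableChangeModel(scores, control, schedule=make_schedule()).fit()
        assert len(res.timepoint_summary) == 8
        assert (res.timepoint_summary["n_total"] == 8).all()
        assert len(res.z_scores) == 8 * 8 * 2 * 2
        assert set(res.anova) == {"accuracy", "rt"}
        text = res.summary()
        assert "RM-ANOVA" in text and "occasion 9" in text

    def test_fit_matches_functional_pipeline(self):
        scores = make_scores(
            n_subjects=6, occasions=(1, 2, 3), tests=("ldt",), prefix="I",
            cohort="intervention", seed=31,
        )
        control = make_scores(n_subjects=5, tests=("ldt",), seed=32)
        res = ReliableChangeModel(scores, control).fit()
        from cogdecline import change_from_baseline, estimate_learning

        z = z_score_table(change_from_baseline(scores), estimate_learning(control))
        pd.testing.assert_frame_equal(res.z_scores, z)
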