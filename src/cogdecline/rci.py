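"""Reliable-change (ISPOCD-style Z score) classification.

For each subject x occasion x test x metric, the change from the subject's
own baseline is corrected for the control cohort's practice (learning)
effect and scaled by the control cohort's SD of change:

    z = (delta - learning_mean) / learning_sd

A subject declines at an occasion when any test's accuracy dropped or RT
rose by more than ``z_threshold`` normative SDs (the ``any_test_metric``
rule; strictly beyond the threshold), or, under the ``composite_mean_z``
rule, when the mean decline-oriented z across tests and metrics exceeds
the threshold — the composite reading of the original reliable-change
methodology.

Two sign conventions are provided.  ``internal`` (default) takes deltas as
follow-up minus baseline, so decline is a negative accuracy z or a positive
RT z.  ``paper`` swaps the two inequalities (accuracy flags at z > +t, RT
at z < -t), reproducing the printed directions of the source analysis under
a baseline-minus-follow-up reading of the same change scores.  The two
conventions are duals: applying ``paper`` to negated deltas equals
``internal`` on the originals.

The module-level functions operate on single records and tables; the
:class:`ReliableChangeModel` / :class:`ReliableChangeResults` pair wraps the
whole analysis (scores in, Z table, per-occasion decline percentages,
group-level change summaries and repeated-measures ANOVA out).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import group as group_stats
from .exceptions import ValidationError
from .learning import estimate_learning, validate_learning
from .schedule import TimepointSchedule
from .scoring import change_from_baseline

COMBINE_RULES = ("any_test_metric", "composite_mean_z")
SIGN_CONVENTIONS = ("internal", "paper")

Z_COLUMNS = ["subject_id", "occasion", "test_id", "metric", "z"]
CLASSIFICATION_COLUMNS = ["subject_id", "occasion", "decline", "triggers"]
SUMMARY_COLUMNS = [
    "occasion",
    "event_label",
    "n_total",
    "n_decline",
    "n_normal",
    "pct_decline",
]


@dataclass(frozen=True)
class ClassificationRule:
    """How per-metric Z scores roll up into a decline verdict."""

    z_threshold: float = 1.96
    combine: str = "any_test_metric"
    sign_convention: str = "internal"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be positive")
        if self.combine not in COMBINE_RULES:
            raise ValidationError(f"combine must be one of {COMBINE_RULES}")
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise ValidationError(f"sign_convention must be one of {SIGN_CONVENTIONS}")


@dataclass(frozen=True)
class DeclineClassification:
    """Decline verdict for one subject x occasion.

    ``triggers`` lists the (test_id, metric, z) entries that crossed the
    threshold under the any-test rule; it is empty iff the subject did not
    decline.  Under the composite rule ``composite_z`` carries the oriented
    mean z and ``triggers`` stays empty.
    """

    subject_id: str
    occasion: int
    decline: bool
    triggers: tuple[tuple[str, str, float], ...] = ()
    composite_z: float | None = None


def z_score(delta: float, mean_change: float, sd_change: float) -> float:
    """Practice-corrected, normatively scaled change: (delta - mean) / sd."""
    if sd_change <= 0:
        raise ValidationError("sd_change must be positive (guard with validate_learning)")
    if not (math.isfinite(delta) and math.isfinite(mean_change)):
        raise ValidationError("delta and mean_change must be finite")
    return (delta - mean_change) / sd_change


def z_score_table(changes: pd.DataFrame, effects: pd.DataFrame) -> pd.DataFrame:
    """Vectorised Z scores for a change table against a learning-effect table.

    Every (test_id, metric) present in ``changes`` must appear in
    ``effects``.
    """
    validate_learning(effects)
    merged = changes.merge(effects, on=["test_id", "metric"], how="left", indicator=True)
    missing = merged[merged["_merge"] != "both"]
    if len(missing):
        keys = sorted(set(zip(missing["test_id"], missing["metric"])))
        raise ValidationError(f"no learning effect for keys: {keys}")
    merged["z"] = (merged["delta"] - merged["mean_change"]) / merged["sd_change"]
    return merged[Z_COLUMNS].sort_values(
        ["subject_id", "occasion", "test_id", "metric"], ignore_index=True
    )


def flag_metric(z: float, metric: str, rule: ClassificationRule) -> bool:
    """Does this Z score indicate decline for its metric?

    Internal convention (deltas = follow-up - baseline): accuracy flags at
    z < -threshold, RT at z > +threshold; the ``paper`` convention swaps the
    inequalities.  Strict at the boundary.
    """
    if metric not in ("accuracy", "rt"):
        raise ValidationError(f"unknown metric {metric!r}")
    t = rule.z_threshold
    if rule.sign_convention == "internal":
        return z < -t if metric == "accuracy" else z > t
    return z > t if metric == "accuracy" else z < -t


def _oriented(z: np.ndarray, metric: np.ndarray, rule: ClassificationRule) -> np.ndarray:
    """Decline-oriented z: larger = worse, under either sign convention."""
    sign = np.where(metric == "accuracy", -1.0, 1.0)
    if rule.sign_convention == "paper":
        sign = -sign
    return sign * z


def classify_subject_timepoint(
    zs: pd.DataFrame, rule: ClassificationRule = ClassificationRule()
) -> DeclineClassification:
    """Combine one subject x occasion's Z scores into a decline verdict."""
    if len(zs) == 0:
        raise ValidationError("cannot classify from an empty Z-score list")
    for key in ("subject_id", "occasion"):
        if zs[key].nunique() != 1:
            raise ValidationError(f"z scores span multiple values of {key}")
    subject_id = zs["subject_id"].iloc[0]
    occasion = int(zs["occasion"].iloc[0])
    if not np.isfinite(zs["z"]).all():
        raise ValidationError("non-finite z scores")
    if rule.combine == "any_test_metric":
        triggers = tuple(
            (r.test_id, r.metric, float(r.z))
            for r in zs.itertuples()
            if flag_metric(float(r.z), r.metric, rule)
        )
        return DeclineClassification(subject_id, occasion, bool(triggers), triggers)
    oriented = _oriented(zs["z"].to_numpy(dtype=float), zs["metric"].to_numpy(), rule)
    composite = float(oriented.mean())
    return DeclineClassification(
        subject_id, occasion, composite > rule.z_threshold, (), composite
    )


def classify_all(
    z_table: pd.DataFrame, rule: ClassificationRule = ClassificationRule()
) -> pd.DataFrame:
    """Classify every subject x occasion of a Z-score table."""
    rows = []
    for (subject, occ), grp in z_table.groupby(["subject_id", "occasion"], sort=True):
        c = classify_subject_timepoint(grp, rule)
        rows.append(
            {
                "subject_id": subject,
                "occasion": int(occ),
                "decline": c.decline,
                "triggers": format_triggers(c.triggers),
                "composite_z": c.composite_z,
            }
        )
    return pd.DataFrame(rows)


def format_triggers(triggers: tuple[tuple[str, str, float], ...]) -> str:
    return ";".join(f"{t}:{m}:{z:.6g}" for t, m, z in triggers)


def round_half_up(x: float) -> int:
    """Nearest-integer rounding with .5 up, as in the printed percentages."""
    return int(math.floor(x + 0.5))


def summarize_timepoints(
    classifications: pd.DataFrame,
    schedule: TimepointSchedule | None = None,
    baseline_occasion: int = 1,
) -> pd.DataFrame:
    """Per-occasion decline counts and percentages (the summary-table analogue).

    Requires every subject classified at every post-baseline occasion; the
    percentage is kept exact here and rounded to the nearest integer only
    when rendered.
    """
    if len(classifications) == 0:
        raise ValidationError("empty classification table")
    subjects = sorted(classifications["subject_id"].unique())
    occasions = sorted(int(o) for o in classifications["occasion"].unique())
    cells = classifications.set_index(["subject_id", "occasion"]).index
    missing = [
        (s, o) for s in subjects for o in occasions if (s, o) not in cells
    ]
    if missing:
        raise ValidationError(f"missing subject x occasion classifications: {missing[:10]}")
    rows = []
    for occ in occasions:
        if occ == baseline_occasion:
            continue
        part = classifications[classifications["occasion"] == occ]
        n_total = len(part)
        n_decline = int(part["decline"].sum())
        label = schedule.label_of(occ) if schedule is not None else f"Occasion {occ}"
        rows.append(
            {
                "occasion": occ,
                "event_label": label,
                "n_total": n_total,
                "n_decline": n_decline,
                "n_normal": n_total - n_decline,
                "pct_decline": 100.0 * n_decline / n_total,
            }
        )
    return pd.DataFrame(rows)[SUMMARY_COLUMNS]


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


@dataclass
class ReliableChangeModel:
    """Practice-corrected reliable-change analysis of a scored battery.

    Parameters
    ----------
    scores
        Intervention score table (one row per subject x occasion x test with
        ``accuracy`` and ``mean_rt``).
    control_scores
        Control score table over repeated attempts of the same battery.
    schedule
        Optional positional schedule supplying occasion labels.
    rule
        Decline classification rule (threshold, combination, sign
        convention).
    baseline_occasion
        Occasion whose scores anchor each subject's change.
    learning_attempts
        The control attempts whose change defines the practice correction.
    conf_level
        Confidence level of the group-summary intervals.
    """

    scores: pd.DataFrame
    control_scores: pd.DataFrame
    schedule: TimepointSchedule | None = None
    rule: ClassificationRule = field(default_factory=ClassificationRule)
    baseline_occasion: int = 1
    learning_attempts: tuple[int, int] = (3, 4)
    conf_level: float = 0.95

    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        control_trials: pd.DataFrame,
        rt_rule: str = "correct_only",
        **kwargs,
    ) -> "ReliableChangeModel":
        """Build the model from trial-level logs, scoring both cohorts."""
        from .scoring import score_battery

        return cls(
            score_battery(trials, rt_rule=rt_rule),
            score_battery(control_trials, rt_rule=rt_rule),
            **kwargs,
        )

    def fit(self) -> "ReliableChangeResults":
        changes = change_from_baseline(self.scores, self.baseline_occasion)
        effects = validate_learning(
            estimate_learning(self.control_scores, *self.learning_attempts)
        )
        z_table = z_score_table(changes, effects)
        classifications = classify_all(z_table, self.rule)
        summary = summarize_timepoints(
            classifications, self.schedule, self.baseline_occasion
        )
        change_summaries = group_stats.change_summary_table(changes, self.conf_level)
        anova = {}
        for metric in ("accuracy", "rt"):
            per_subject = (
                changes[changes["metric"] == metric]
                .groupby(["subject_id", "occasion"], sort=True)["delta"]
                .mean()
                .reset_index()
            )
            anova[metric] = group_stats.rm_anova(
                per_subject, value_col="delta", subject_col="subject_id", within_col="occasion"
            )
        return ReliableChangeResults(
            model=self,
            learning_effects=effects,
            changes=changes,
            z_scores=z_table,
            classifications=classifications,
            timepoint_summary=summary,
            change_summaries=change_summaries,
            anova=anova,
        )


@dataclass
class ReliableChangeResults:
    """Fitted reliable-change analysis.

    Attributes hold the practice-effect table, change records, Z scores,
    per-subject classifications, the per-occasion decline summary, the
    per-occasion group change summaries and the repeated-measures ANOVA per
    metric.
    """

    model: ReliableChangeModel
    learning_effects: pd.DataFrame
    changes: pd.DataFrame
    z_scores: pd.DataFrame
    classifications: pd.DataFrame
    timepoint_summary: pd.DataFrame
    change_summaries: pd.DataFrame
    anova: dict[str, group_stats.RMAnovaResult]

    @property
    def pct_decline(self) -> pd.Series:
        """Exact percentage of subjects declining per post-baseline occasion."""
        return self.timepoint_summary.set_index("occasion")["pct_decline"]

    def summary(self) -> str:
        """Readable multi-table summary of the fitted analysis."""
        lines = ["Reliable-change analysis", "=" * 24, ""]
        r = self.model.rule
        lines.append(
            f"Rule: |z| > {r.z_threshold:g}, combine={r.combine}, "
            f"sign_convention={r.sign_convention}; "
            f"practice correction from control attempts "
            f"{self.model.learning_attempts[0]}->{self.model.learning_attempts[1]} "
            f"(n={int(self.learning_effects['n_control'].iloc[0])})"
        )
        lines.append("")
        lines.append("Decline by occasion (n, nearest-integer %):")
        for row in self.timepoint_summary.itertuples():
            lines.append(
                f"  occasion {row.occasion}: {row.n_decline}/{row.n_total} "
                f"({round_half_up(row.pct_decline)}%)  {row.event_label}"
            )
        lines.append("")
        for metric in ("accuracy", "rt"):
            a = self.anova[metric]
            lines.append(
                f"RM-ANOVA ({metric} change): F({a.df1:g}, {a.df2:g}) = "
                f"{a.f_value:.3f}, p = {a.p_value:.4g}"
            )
        lines.append("")
        lines.append("Mean change from baseline (95% CI; paired p):")
        for row in self.change_summaries.itertuples():
            lines.append(
                f"  occasion {row.occasion} {row.metric}: {row.mean_change:+.4f} "
                f"({row.ci_low:+.4f} to {row.ci_high:+.4f}), p = {row.p_value:.4g}"
            )
        return "\n".join(lines)
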