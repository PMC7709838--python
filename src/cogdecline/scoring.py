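"""Reduce trial-level logs to per-cell scores and change-from-baseline records.

A "cell" is one subject x occasion x test sitting.  Its score is the
proportion of scorable trials answered correctly and the mean response time,
by default over correct scorable trials only (`correct_only`, the usual
convention in cognitive psychometrics), optionally over all scorable trials
(`all_scorable`).  Change records subtract each subject's own baseline score
from every later occasion, separately for the accuracy and RT metrics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats.mstats import winsorize as _winsorize

from .exceptions import ScoringError, ValidationError

RT_RULES = ("correct_only", "all_scorable")
METRICS = ("accuracy", "rt")

SCORE_COLUMNS = ["subject_id", "cohort", "occasion", "test_id", "accuracy", "mean_rt", "n_scorable"]
CHANGE_COLUMNS = ["subject_id", "occasion", "test_id", "metric", "delta"]


@dataclass(frozen=True)
class TestScore:
    """Score of one cell: accuracy in [0,1] and mean RT in seconds."""

    subject_id: str
    cohort: str
    occasion: int
    test_id: str
    accuracy: float
    mean_rt: float
    n_scorable: int


def _check_rt_rule(rt_rule: str) -> None:
    if rt_rule not in RT_RULES:
        raise ValidationError(f"unknown rt_rule {rt_rule!r}; expected one of {RT_RULES}")


def score_test(
    trials: pd.DataFrame, rt_rule: str = "correct_only", winsorize_rt: float | None = None
) -> TestScore:
    """Score the trials of a single cell.

    Parameters
    ----------
    trials
        Trial rows sharing one (subject, occasion, test); must contain the
        columns ``scorable``, ``response_correct`` and ``rt_seconds``.
    rt_rule
        ``correct_only`` averages RT over correct scorable trials (errors if
        there are none); ``all_scorable`` averages over every scorable trial.
    winsorize_rt
        Optional symmetric winsorizing fraction applied to the RTs entering
        the mean; off by default (no trimming).

    Raises
    ------
    ScoringError
        On an empty cell, zero scorable trials, or zero correct trials under
        ``correct_only``.
    """
    _check_rt_rule(rt_rule)
    if len(trials) == 0:
        raise ScoringError("cannot score an empty trial list")
    for key in ("subject_id", "occasion", "test_id"):
        if trials[key].nunique() != 1:
            raise ValidationError(f"trials span multiple values of {key}")
    subject_id = trials["subject_id"].iloc[0]
    occasion = int(trials["occasion"].iloc[0])
    test_id = trials["test_id"].iloc[0]
    cohort = trials["cohort"].iloc[0] if "cohort" in trials else "intervention"

    scorable = trials.loc[trials["scorable"].astype(bool)]
    n_scorable = len(scorable)
    if n_scorable == 0:
        raise ScoringError(f"no scorable trials for ({subject_id}, {occasion}, {test_id})")
    correct = scorable["response_correct"].astype(bool)
    accuracy = float(correct.sum()) / n_scorable
    if rt_rule == "correct_only":
        rts = scorable.loc[correct, "rt_seconds"].to_numpy(dtype=float)
        if rts.size == 0:
            raise ScoringError(
                f"no correct scorable trials for ({subject_id}, {occasion}, {test_id}) "
                "under rt_rule='correct_only'"
            )
    else:
        rts = scorable["rt_seconds"].to_numpy(dtype=float)
    if winsorize_rt:
        rts = np.asarray(_winsorize(rts, limits=(winsorize_rt, winsorize_rt)))
    return TestScore(subject_id, cohort, occasion, test_id, accuracy, float(rts.mean()), n_scorable)


def score_battery(
    trials: pd.DataFrame, rt_rule: str = "correct_only", winsorize_rt: float | None = None
) -> pd.DataFrame:
    """Score every (subject, occasion, test) cell of a trial table.

    Returns one row per cell, sorted by (subject_id, occasion, test_id).
    Scoring errors are re-raised naming the offending cell.
    """
    _check_rt_rule(rt_rule)
    if len(trials) == 0:
        raise ValidationError("trial table is empty")
    rows = []
    for _, group in trials.groupby(["subject_id", "occasion", "test_id"], sort=True):
        score = score_test(group, rt_rule=rt_rule, winsorize_rt=winsorize_rt)
        rows.append(score.__dict__)
    return pd.DataFrame(rows)[SCORE_COLUMNS].sort_values(
        ["subject_id", "occasion", "test_id"], ignore_index=True
    )


def change_from_baseline(scores: pd.DataFrame, baseline_occasion: int = 1) -> pd.DataFrame:
    """Subtract each subject's own baseline score from every later occasion.

    Produces two change records (metrics ``accuracy`` and ``rt``) per
    subject x test x post-baseline occasion, with
    ``delta = value(occasion) - value(baseline)`` in the metric's units.

    Raises
    ------
    ValidationError
        If any subject x test lacks a score at ``baseline_occasion``.
    """
    if len(scores) == 0:
        raise ValidationError("score table is empty")
    base = scores[scores["occasion"] == baseline_occasion]
    follow = scores[scores["occasion"] != baseline_occasion]
    pairs = scores[["subject_id", "test_id"]].drop_duplicates()
    have = base[["subject_id", "test_id"]].drop_duplicates()
    missing = pairs.merge(have, how="left", indicator=True).query("_merge == 'left_only'")
    if len(missing):
        items = ", ".join(
            f"({r.subject_id}, {r.test_id})" for r in missing.itertuples()
        )
        raise ValidationError(
            f"missing baseline (occasion {baseline_occasion}) scores for: {items}"
        )
    merged = follow.merge(
        base[["subject_id", "test_id", "accuracy", "mean_rt"]],
        on=["subject_id", "test_id"],
        suffixes=("", "_baseline"),
    )
    out = []
    for metric, col in (("accuracy", "accuracy"), ("rt", "mean_rt")):
        part = merged[["subject_id", "occasion", "test_id"]].copy()
        part["metric"] = metric
        part["delta"] = merged[col] - merged[f"{col}_baseline"]
        out.append(part)
    changes = pd.concat(out, ignore_index=True)
    if not np.isfinite(changes["delta"]).all():
        raise ValidationError("non-finite change values")
    return changes.sort_values(
        ["subject_id", "occasion", "test_id", "metric"], ignore_index=True
    )[CHANGE_COLUMNS]
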