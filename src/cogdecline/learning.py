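"""Practice ("learning") effect estimation from the control cohort.

Repeated administration of the same cognitive test improves scores even
without any intervention.  Following the reliable-change convention, the
correction is estimated from a control cohort that sat the battery several
times: per test and metric, the mean and sample SD of the change between
the third and fourth attempt.  The mean is the practice correction
subtracted from every intervention change score; the SD is the normative
denominator of the Z score.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateNormativeError, ValidationError
from .scoring import METRICS

LEARNING_COLUMNS = ["test_id", "metric", "mean_change", "sd_change", "n_control"]

_METRIC_COL = {"accuracy": "accuracy", "rt": "mean_rt"}


def estimate_learning(
    control_scores: pd.DataFrame, from_attempt: int = 3, to_attempt: int = 4
) -> pd.DataFrame:
    """Estimate per test x metric practice effects from control scores.

    ``mean_change`` is the mean over control subjects of
    ``value(to_attempt) - value(from_attempt)``; ``sd_change`` the sample SD
    (n-1 denominator) of those per-subject changes.

    Raises
    ------
    ValidationError
        If any control subject lacks a score at either attempt for any
        test, or fewer than two control subjects are present (SD undefined).
    """
    if from_attempt == to_attempt:
        raise ValidationError("from_attempt and to_attempt must differ")
    pivot = {}
    for attempt in (from_attempt, to_attempt):
        part = control_scores[control_scores["occasion"] == attempt]
        pivot[attempt] = part.set_index(["subject_id", "test_id"])
    tests = sorted(control_scores["test_id"].unique())
    subjects = sorted(control_scores["subject_id"].unique())
    missing = []
    for attempt in (from_attempt, to_attempt):
        idx = pivot[attempt].index
        for s in subjects:
            for t in tests:
                if (s, t) not in idx:
                    missing.append((s, t, attempt))
    if missing:
        items = ", ".join(f"({s}, {t}, attempt {a})" for s, t, a in missing[:10])
        raise ValidationError(f"control scores missing at required attempts: {items}")
    if len(subjects) < 2:
        raise ValidationError(
            f"need >= 2 control subjects for a defined change SD; got {len(subjects)}"
        )
    rows = []
    for t in tests:
        for metric in METRICS:
            col = _METRIC_COL[metric]
            changes = np.array(
                [
                    pivot[to_attempt].loc[(s, t), col] - pivot[from_attempt].loc[(s, t), col]
                    for s in subjects
                ],
                dtype=float,
            )
            rows.append(
                {
                    "test_id": t,
                    "metric": metric,
                    "mean_change": float(changes.mean()),
                    "sd_change": float(changes.std(ddof=1)),
                    "n_control": len(subjects),
                }
            )
    return pd.DataFrame(rows)[LEARNING_COLUMNS]


def validate_learning(effects: pd.DataFrame, sd_floor: float = 1e-9) -> pd.DataFrame:
    """Guard the Z-score denominator against degenerate normative data.

    Passes the table through unchanged when every ``sd_change`` is at least
    ``sd_floor``; otherwise raises naming the degenerate test x metric.
    A genuinely zero change SD signals a broken normative sample, not a
    small-variance population.
    """
    if sd_floor <= 0:
        raise ValidationError("sd_floor must be positive")
    bad = effects[effects["sd_change"] < sd_floor]
    if len(bad):
        items = ", ".join(
            f"({r.test_id}, {r.metric}: sd={r.sd_change:g})" for r in bad.itertuples()
        )
        raise DegenerateNormativeError(
            f"normative change SD below floor {sd_floor:g} for: {items}"
        )
    return effects
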