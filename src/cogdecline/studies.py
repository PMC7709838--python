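"""Replicated simulation studies validating the classifier.

These are the package's built-in calibration and sensitivity studies:

* :func:`null_calibration_study` — under a zero-decline, zero-practice
  scenario the practice-corrected Z criterion should flag each metric at
  the one-sided normal tail rate (about 2.5% at threshold 1.96) when the
  normative (control) sample is large; with a small normative sample the
  Z denominator is noisy and the flag rate is inflated.
* :func:`recovery_study` — injecting progressively larger RT decline
  shifts must produce non-decreasing flagged percentages.

Both run the full estimation path (scores -> changes -> learning effect ->
Z -> flags) on score-level simulations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import calibration_scenario, simulate_scores
from .learning import estimate_learning
from .rci import ClassificationRule, classify_all, summarize_timepoints, z_score_table
from .scoring import change_from_baseline


def _flag_rates(z_table: pd.DataFrame, rule: ClassificationRule) -> dict[str, float]:
    """Per-metric fraction of Z scores crossing the decline threshold."""
    out = {}
    for metric, sign in (("accuracy", -1.0), ("rt", 1.0)):
        z = z_table.loc[z_table["metric"] == metric, "z"].to_numpy()
        s = sign if rule.sign_convention == "internal" else -sign
        out[metric] = float((s * z > rule.z_threshold).mean())
    return out


def replicate_flag_rates(
    n_intervention: int,
    n_control: int,
    n_replicates: int,
    n_trials: int = 300,
    base_seed: int = 0,
    rule: ClassificationRule = ClassificationRule(),
) -> pd.DataFrame:
    """Per-replicate per-metric flag rates under the exact null.

    Each replicate simulates a fresh zero-effect cohort pair (seed
    ``base_seed + r``), estimates the learning correction from its own
    control cohort and measures the fraction of post-baseline Z scores
    flagged, per metric, across all tests and occasions.
    """
    rows = []
    for r in range(n_replicates):
        config = calibration_scenario(
            n_intervention, n_control, n_trials=n_trials, seed=base_seed + r
        )
        scores, control_scores, _ = simulate_scores(config)
        z = z_score_table(
            change_from_baseline(scores), estimate_learning(control_scores)
        )
        rates = _flag_rates(z, rule)
        rows.append({"replicate": r, **rates})
    return pd.DataFrame(rows)


def null_calibration_study(
    n_intervention: int = 500,
    n_control: int = 200,
    n_replicates: int = 20,
    n_small_control: int = 5,
    n_trials: int = 300,
    base_seed: int = 0,
) -> dict:
    """Null flag-rate calibration with large and small normative samples.

    Returns per-metric mean rates, their Monte-Carlo standard errors (from
    the replicate spread) for the large-control arm, and the small-control
    mean rates for the inflation comparison.
    """
    large = replicate_flag_rates(
        n_intervention, n_control, n_replicates, n_trials, base_seed
    )
    small = replicate_flag_rates(
        n_intervention, n_small_control, n_replicates, n_trials, base_seed + 10_000
    )
    out: dict = {"n_replicates": n_replicates}
    for metric in ("accuracy", "rt"):
        vals = large[metric].to_numpy()
        out[metric] = {
            "rate": float(vals.mean()),
            "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
            "rate_small_control": float(small[metric].mean()),
        }
    return out


def recovery_study(
    shifts: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2),
    n_intervention: int = 100,
    n_control: int = 50,
    n_replicates: int = 3,
    n_trials: int = 150,
    base_seed: int = 0,
    rule: ClassificationRule = ClassificationRule(),
) -> pd.DataFrame:
    """Mean declined percentage as a function of the injected RT shift.

    Every intervention subject receives the same log-RT shift at every
    post-baseline occasion; the declined percentage is averaged over
    post-baseline occasions and replicates.  The same replicate seeds are
    used at every grid point so the grid differs only in the injected
    effect.
    """
    rows = []
    for shift in shifts:
        pcts = []
        for r in range(n_replicates):
            config = calibration_scenario(
                n_intervention,
                n_control,
                n_trials=n_trials,
                seed=base_seed + r,
                decline_rt_log=shift,
            )
            scores, control_scores, _ = simulate_scores(config)
            z = z_score_table(
                change_from_baseline(scores), estimate_learning(control_scores)
            )
            summary = summarize_timepoints(classify_all(z, rule))
            pcts.append(float(summary["pct_decline"].mean()))
        rows.append({"rt_log_shift": shift, "mean_pct_decline": float(np.mean(pcts))})
    return pd.DataFrame(rows)
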