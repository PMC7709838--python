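"""Group-level repeated-measures summaries and power/sample-size computation.

Per-occasion paired summaries (mean change from baseline with a t-based 95%
CI and a two-sided paired t-test against zero), a one-way within-subject
repeated-measures ANOVA with optional Greenhouse-Geisser correction, and
the normal-approximation two-sample-means sample size / achieved power.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .exceptions import ValidationError


@dataclass(frozen=True)
class ChangeSummary:
    """Mean change from baseline at one occasion with 95% CI and paired p."""

    occasion: int
    metric: str
    mean_change: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sample-means sample size computation.

    ``mu1/sd1`` and ``mu2/sd2`` are the two group means and SDs in the same
    units; ``alpha`` is two-sided.  ``rounding`` controls how the raw
    (non-integer) n per group is reported.
    """

    mu1: float
    sd1: float
    mu2: float
    sd2: float
    alpha: float = 0.05
    power: float = 0.80
    rounding: str = "floor"

    def __post_init__(self) -> None:
        if self.mu1 == self.mu2:
            raise ValidationError("mu1 and mu2 must differ")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValidationError("sd1 and sd2 must be positive")
        if not (0.0 < self.alpha < 1.0) or not (0.0 < self.power < 1.0):
            raise ValidationError("alpha and power must lie in (0, 1)")
        if self.rounding not in ("floor", "ceil", "nearest"):
            raise ValidationError("rounding must be floor, ceil or nearest")
        if self.alpha >= 1.0 - self.power:
            warnings.warn(
                "alpha >= 1 - power: unusually permissive design", stacklevel=2
            )


@dataclass(frozen=True)
class RMAnovaResult:
    """One-way within-subject ANOVA: F = MS_occasion / MS_(occasion x subject)."""

    f_value: float
    df1: float
    df2: float
    p_value: float
    gg_epsilon: float | None = None


def paired_change_summary(
    deltas, occasion: int = 0, metric: str = "", conf_level: float = 0.95
) -> ChangeSummary:
    """Summarise one occasion x metric's change-from-baseline values.

    ``mean ± t_{(1-conf)/2, n-1} * sd / sqrt(n)`` for the CI and a two-sided
    one-sample t-test of the deltas against zero.  With zero variance the
    t statistic is undefined: p is 1 when the mean is also zero (no change
    at all), and an error otherwise.
    """
    x = np.asarray(deltas, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("need at least 2 delta values")
    if not np.isfinite(x).all():
        raise ValidationError("deltas must be finite")
    if not (0.0 < conf_level < 1.0):
        raise ValidationError("conf_level must lie in (0, 1)")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return ChangeSummary(occasion, metric, 0.0, 0.0, 0.0, 1.0, n)
        raise ValidationError(
            "zero-variance deltas with nonzero mean: t statistic undefined"
        )
    half = stats.t.ppf(0.5 + conf_level / 2.0, n - 1) * sd / math.sqrt(n)
    t_stat = mean / (sd / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    return ChangeSummary(occasion, metric, mean, mean - half, mean + half, p, n)


def change_summary_table(changes: pd.DataFrame, conf_level: float = 0.95) -> pd.DataFrame:
    """Per occasion x metric paired summaries of a change-record table.

    Deltas are first averaged over tests within subject, so each subject
    contributes one value per occasion x metric (the battery-level change
    analysed in a repeated-measures layout).
    """
    per_subject = (
        changes.groupby(["occasion", "metric", "subject_id"], sort=True)["delta"]
        .mean()
        .reset_index()
    )
    rows = []
    for (occ, metric), grp in per_subject.groupby(["occasion", "metric"], sort=True):
        s = paired_change_summary(
            grp["delta"].to_numpy(), occasion=int(occ), metric=metric, conf_level=conf_level
        )
        rows.append(s.__dict__)
    return pd.DataFrame(rows)


def rm_anova(
    data: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = "subject_id",
    within_col: str = "occasion",
    greenhouse_geisser: bool = False,
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with subject as the blocking factor.

    Requires a balanced subject x occasion grid.  ``greenhouse_geisser``
    multiplies both degrees of freedom by the Greenhouse-Geisser epsilon
    computed from the double-centred occasion covariance matrix.
    """
    wide = data.pivot(index=subject_col, columns=within_col, values=value_col)
    if wide.isna().any().any():
        raise ValidationError("unbalanced subject x occasion grid (missing cells)")
    n, k = wide.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 occasions")
    values = wide.to_numpy(dtype=float)

    # sums of squares, used for the degenerate guard (statsmodels returns
    # NaN when MS_error is 0)
    grand = values.mean()
    ss_occ = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_sub = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    ss_err = ss_tot - ss_occ - ss_sub
    df1, df2 = float(k - 1), float((k - 1) * (n - 1))
    tol = 1e-12 * max(1.0, abs(grand)) ** 2 * n * k
    if ss_err <= tol:
        if ss_occ <= tol:
            return RMAnovaResult(0.0, df1, df2, 1.0)
        return RMAnovaResult(float("inf"), df1, df2, 0.0)

    long = wide.reset_index().melt(
        id_vars=subject_col, var_name=within_col, value_name=value_col
    )
    fit = AnovaRM(long, depvar=value_col, subject=subject_col, within=[within_col]).fit()
    row = fit.anova_table.iloc[0]
    f_value = float(row["F Value"])
    df1, df2 = float(row["Num DF"]), float(row["Den DF"])
    p = float(row["Pr > F"])
    eps = None
    if greenhouse_geisser:
        eps = _gg_epsilon(values)
        df1, df2 = df1 * eps, df2 * eps
        p = float(stats.f.sf(f_value, df1, df2))
    return RMAnovaResult(f_value, df1, df2, p, eps)


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance matrix."""
    k = values.shape[1]
    cov = np.cov(values, rowvar=False, ddof=1)
    centred = cov - cov.mean(axis=0, keepdims=True) - cov.mean(axis=1, keepdims=True) + cov.mean()
    num = np.trace(centred) ** 2
    den = (k - 1) * (centred**2).sum()
    eps = float(num / den)
    return min(1.0, max(eps, 1.0 / (k - 1)))


def sample_size_two_means(spec: PowerSpec) -> int:
    """Normal-approximation n per group to detect ``mu1 - mu2``.

    ``n_raw = (z_{1-alpha/2} + z_power)^2 (sd1^2 + sd2^2) / (mu1 - mu2)^2``,
    with the configured rounding applied and a minimum of 2 per group.
    """
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_power = stats.norm.ppf(spec.power)
    n_raw = (z_alpha + z_power) ** 2 * (spec.sd1**2 + spec.sd2**2) / (spec.mu1 - spec.mu2) ** 2
    if spec.rounding == "floor":
        n = math.floor(n_raw)
    elif spec.rounding == "ceil":
        n = math.ceil(n_raw)
    else:
        n = math.floor(n_raw + 0.5)
    return max(2, int(n))


def achieved_power(
    n_per_group: float, mu1: float, sd1: float, mu2: float, sd2: float, alpha: float = 0.05
) -> float:
    """Normal-approximation power of a two-sample-means comparison at n per group."""
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if sd1 <= 0 or sd2 <= 0 or not (0.0 < alpha < 1.0):
        raise ValidationError("invalid sd or alpha")
    se = math.sqrt((sd1**2 + sd2**2) / n_per_group)
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(mu1 - mu2) / se - z_alpha))
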