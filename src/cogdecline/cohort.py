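"""Synthetic cohort generator.

Simulates trial-level battery data for an intervention cohort tested over
the 9-occasion positional schedule and a seated control cohort tested over
four repeated sittings, with known injected practice (learning) and
position-dependent decline effects, so that downstream estimators can be
validated against ground truth.

Response model
--------------
For a subject with latent ability ``a`` (logit scale) and latent speed
``s`` (log-seconds scale), on a test with difficulty ``d`` and log-RT
offset ``o``, after ``m`` prior administrations and with injected shifts
``(u, v)`` (log-RT, accuracy-logit):

* ``P(correct) = logistic(a - d + g_acc * m + v)``
* ``RT = t0 + exp(s + o + g_rt * m + u + sigma * eps)``, ``eps ~ N(0, 1)``

``g_acc`` and ``g_rt`` are the per-attempt practice effects, ``t0`` a
non-decision shift and ``sigma`` the trial-level log-RT noise.  Accuracy
improves and RTs shorten with practice when ``g_acc > 0 > g_rt``; a
positional decline makes ``u > 0`` (slower) and ``v < 0`` (less accurate).

A configurable fraction of intervention subjects is "susceptible": their
injected shifts are multiplied by ``susceptibility_multiplier``, creating
the subject heterogeneity that lets a subset of the cohort cross the
reliable-change threshold.  Controls are seated throughout and receive no
positional shifts, only practice.

Randomness is a single integer seed split hierarchically per
(cohort, subject, occasion, test), so changing one test's trial count does
not perturb any other cell.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError, ScoringError
from .schedule import TimepointSchedule, make_schedule
from .tasks import TestSpec, default_battery
from .tasks import _stimulus_arrays

_COHORT_CODE = {"intervention": 1, "control": 2}
_LATENT_TAG = 101
_CELL_TAG = 202
_STATE_TAG = 303

TRIAL_COLUMNS = [
    "subject_id",
    "cohort",
    "occasion",
    "test_id",
    "trial_index",
    "stimulus_kind",
    "scorable",
    "response_correct",
    "rt_seconds",
]


class DeclineShift(NamedTuple):
    """Injected per-occasion decline: log-RT shift (+ = slower) and accuracy logit shift (- = worse)."""

    rt_log_shift: float = 0.0
    accuracy_logit_shift: float = 0.0


#: Decline profile used by the paper-like demonstration scenario: RT slows
#: progressively with time head-down, peaks after 3 h, partially recovers
#: supine and worsens slightly again on sitting up; accuracy shifts are small.
DEFAULT_DECLINE_PROFILE: dict[int, DeclineShift] = {
    2: DeclineShift(0.04, -0.05),
    3: DeclineShift(0.05, -0.06),
    4: DeclineShift(0.06, -0.07),
    5: DeclineShift(0.07, -0.08),
    6: DeclineShift(0.08, -0.09),
    7: DeclineShift(0.10, -0.12),
    8: DeclineShift(0.08, -0.09),
    9: DeclineShift(0.09, -0.10),
}


def _as_shift(value) -> DeclineShift:
    if isinstance(value, DeclineShift):
        return value
    if isinstance(value, Mapping):
        return DeclineShift(
            float(value.get("rt_log_shift", 0.0)),
            float(value.get("accuracy_logit_shift", 0.0)),
        )
    rt, acc = value
    return DeclineShift(float(rt), float(acc))


@dataclass
class ScenarioConfig:
    """Full generative specification of a synthetic cohort.

    The defaults reproduce the study conditions this package emulates:
    15 intervention subjects over the 9-occasion positional schedule and
    5 controls over 4 repeated sittings, a five-test battery, a modest
    per-attempt practice effect, a rising RT-dominant decline profile and a
    third of subjects susceptible (receiving the shifts multiplied by
    ``susceptibility_multiplier``).
    """

    n_intervention: int = 15
    n_control: int = 5
    schedule: TimepointSchedule = field(default_factory=make_schedule)
    test_specs: tuple[TestSpec, ...] = field(default_factory=default_battery)
    practice_gain_logit: float = 0.03
    practice_rt_log: float = -0.01
    decline_profile: dict[int, DeclineShift] = field(
        default_factory=lambda: dict(DEFAULT_DECLINE_PROFILE)
    )
    susceptible_fraction: float = 1.0 / 3.0
    susceptibility_multiplier: float = 3.5
    ability_mean_logit: float = 0.0
    speed_mean_log: float = 0.0
    subject_sd_logit: float = 0.5
    subject_sd_rt_log: float = 0.12
    occasion_sd_logit: float = 0.15
    occasion_sd_rt_log: float = 0.06
    rt_sigma_log: float = 0.3
    rt_shift_seconds: float = 0.2
    n_control_attempts: int = 4
    practice_runs_before_baseline: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervention < 1 or self.n_control < 1:
            raise ConfigurationError("cohort sizes must be positive")
        if not isinstance(self.schedule, TimepointSchedule):
            raise ConfigurationError("schedule must be a TimepointSchedule")
        self.test_specs = tuple(self.test_specs)
        if not self.test_specs:
            raise ConfigurationError("at least one TestSpec required")
        ids = [t.test_id for t in self.test_specs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate test_id in test_specs")
        if not (0.0 <= self.susceptible_fraction <= 1.0):
            raise ConfigurationError("susceptible_fraction must lie in [0, 1]")
        if self.susceptibility_multiplier < 1.0:
            raise ConfigurationError("susceptibility_multiplier must be >= 1")
        for name in (
            "subject_sd_logit",
            "subject_sd_rt_log",
            "occasion_sd_logit",
            "occasion_sd_rt_log",
            "rt_shift_seconds",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.rt_sigma_log <= 0:
            raise ConfigurationError("rt_sigma_log must be positive")
        if self.n_control_attempts < 2:
            raise ConfigurationError("controls need at least 2 attempts")
        profile = {int(k): _as_shift(v) for k, v in self.decline_profile.items()}
        valid = set(self.schedule.indices)
        for occ, shift in profile.items():
            if occ not in valid:
                raise ConfigurationError(f"decline profile occasion {occ} not in schedule")
            if occ == 1 and (shift.rt_log_shift != 0.0 or shift.accuracy_logit_shift != 0.0):
                raise ConfigurationError("decline shifts must be zero at the baseline occasion")
            for v in shift:
                if not math.isfinite(v):
                    raise ConfigurationError("decline shifts must be finite")
        self.decline_profile = profile

    # -- RNG plumbing --------------------------------------------------

    def _subject_rng(self, cohort: str, subject_index: int) -> np.random.Generator:
        ss = np.random.SeedSequence(
            [int(self.seed), _COHORT_CODE[cohort], subject_index, _LATENT_TAG]
        )
        return np.random.default_rng(ss)

    def _cell_rng(
        self, cohort: str, subject_index: int, occasion: int, test_index: int
    ) -> np.random.Generator:
        ss = np.random.SeedSequence(
            [int(self.seed), _COHORT_CODE[cohort], subject_index, occasion, test_index, _CELL_TAG]
        )
        return np.random.default_rng(ss)

    def _state_rng(self, cohort: str, subject_index: int, occasion: int) -> np.random.Generator:
        ss = np.random.SeedSequence(
            [int(self.seed), _COHORT_CODE[cohort], subject_index, occasion, _STATE_TAG]
        )
        return np.random.default_rng(ss)

    def subject_ids(self, cohort: str) -> list[str]:
        n = self.n_intervention if cohort == "intervention" else self.n_control
        width = max(2, len(str(n)))
        prefix = "I" if cohort == "intervention" else "C"
        return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def calibration_scenario(
    n_intervention: int,
    n_control: int,
    n_trials: int = 300,
    seed: int = 0,
    decline_rt_log: float = 0.0,
    decline_accuracy_logit: float = 0.0,
) -> ScenarioConfig:
    """Scenario for classifier calibration and recovery studies.

    Practice effects are zero in both cohorts (the one-step learning
    correction is then exactly centred at every occasion), all five tests
    share a mid-range difficulty (about 77% accuracy) so proportion scores
    are effectively continuous at ``n_trials=300``, and an identical decline
    shift is applied to every intervention subject at every post-baseline
    occasion (``susceptible_fraction=0``, so the grid value is the effect).
    With both shifts zero this is an exact null: every post-baseline
    occasion's per-metric flag rate estimates the one-sided normal tail.
    """
    specs = tuple(
        TestSpec(tid, n_trials=n_trials, difficulty_logit=1.2, log_rt_offset=-0.6)
        for tid in ("nback1", "nback2", "nback3", "stroop", "ldt")
    )
    shift = DeclineShift(decline_rt_log, decline_accuracy_logit)
    profile = {occ: shift for occ in range(2, 10)}
    return ScenarioConfig(
        n_intervention=n_intervention,
        n_control=n_control,
        test_specs=specs,
        practice_gain_logit=0.0,
        practice_rt_log=0.0,
        decline_profile=profile,
        susceptible_fraction=0.0,
        susceptibility_multiplier=1.0,
        subject_sd_logit=0.4,
        seed=seed,
    )


@dataclass(frozen=True)
class SubjectLatents:
    subject_id: str
    cohort: str
    susceptible: bool
    ability_logit: float
    speed_log: float


def draw_subject_latents(config: ScenarioConfig, cohort: str, subject_index: int) -> SubjectLatents:
    """Draw a subject's latent ability/speed intercepts and susceptibility flag."""
    rng = config._subject_rng(cohort, subject_index)
    ability = config.ability_mean_logit + config.subject_sd_logit * rng.standard_normal()
    speed = config.speed_mean_log + config.subject_sd_rt_log * rng.standard_normal()
    susceptible = bool(cohort == "intervention" and rng.random() < config.susceptible_fraction)
    return SubjectLatents(
        config.subject_ids(cohort)[subject_index], cohort, susceptible, ability, speed
    )


def _cell_draws(
    rng: np.random.Generator,
    spec: TestSpec,
    p_correct: float,
    mu_log_rt: float,
    sigma: float,
    rt_shift: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Shared per-cell kernel: stimuli, then correctness, then RT noise.

    The draw order is part of the reproducibility contract: both the
    trial-level and the score-level generators consume the identical
    stream.  Returns (stimulus, kind, scorable, correct, rt) arrays.
    """
    stimulus, kind, scorable = _stimulus_arrays(spec, rng)
    correct = rng.random(spec.n_trials) < p_correct
    rt = rt_shift + np.exp(mu_log_rt + sigma * rng.standard_normal(spec.n_trials))
    return stimulus, kind, scorable, correct, rt


def simulate_subject_occasion(
    latents: SubjectLatents,
    spec: TestSpec,
    occasion: int,
    prior_attempts: int,
    *,
    practice_gain_logit: float = 0.0,
    practice_rt_log: float = 0.0,
    rt_log_shift: float = 0.0,
    accuracy_logit_shift: float = 0.0,
    rt_sigma_log: float = 0.3,
    rt_shift_seconds: float = 0.2,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one subject sitting one test once; returns trial rows.

    ``prior_attempts`` counts every earlier administration of this test
    (practice runs included), which scales the linear practice effect.
    """
    params = (
        practice_gain_logit,
        practice_rt_log,
        rt_log_shift,
        accuracy_logit_shift,
        latents.ability_logit,
        latents.speed_log,
    )
    if not all(math.isfinite(p) for p in params):
        raise ConfigurationError("response-model parameters must be finite")
    p_correct = float(
        expit(
            latents.ability_logit
            - spec.difficulty_logit
            + practice_gain_logit * prior_attempts
            + accuracy_logit_shift
        )
    )
    mu = (
        latents.speed_log
        + spec.log_rt_offset
        + practice_rt_log * prior_attempts
        + rt_log_shift
    )
    stimulus, kind, scorable, correct, rt = _cell_draws(
        rng, spec, p_correct, mu, rt_sigma_log, rt_shift_seconds
    )
    return pd.DataFrame(
        {
            "subject_id": latents.subject_id,
            "cohort": latents.cohort,
            "occasion": occasion,
            "test_id": spec.test_id,
            "trial_index": np.arange(spec.n_trials),
            "stimulus_kind": kind,
            "scorable": scorable,
            "response_correct": correct,
            "rt_seconds": rt,
            "stimulus": stimulus,
        }
    )[TRIAL_COLUMNS + ["stimulus"]]


def _iter_cells(config: ScenarioConfig):
    """Yield (latents, spec, occasion, shifts, stim, correct, rt) per cell in canonical order."""
    sigma = config.rt_sigma_log
    t0 = config.rt_shift_seconds
    for cohort in ("intervention", "control"):
        n_sub = config.n_intervention if cohort == "intervention" else config.n_control
        if cohort == "intervention":
            occasions = list(config.schedule.indices)
        else:
            occasions = list(range(1, config.n_control_attempts + 1))
        for si in range(n_sub):
            lat = draw_subject_latents(config, cohort, si)
            for occ in occasions:
                if cohort == "intervention":
                    prior = config.practice_runs_before_baseline + (occ - 1)
                    shift = config.decline_profile.get(occ, DeclineShift())
                    if lat.susceptible:
                        shift = DeclineShift(
                            shift.rt_log_shift * config.susceptibility_multiplier,
                            shift.accuracy_logit_shift * config.susceptibility_multiplier,
                        )
                else:
                    prior = occ - 1
                    shift = DeclineShift()
                # "day-form" state of this sitting, shared across the battery's
                # tests and present in both cohorts: correlates per-test scores
                # within an occasion without touching per-metric calibration
                state_rng = config._state_rng(cohort, si, occ)
                state_logit = config.occasion_sd_logit * state_rng.standard_normal()
                state_rt_log = config.occasion_sd_rt_log * state_rng.standard_normal()
                state = (state_logit, state_rt_log)
                for ti, spec in enumerate(config.test_specs):
                    rng = config._cell_rng(cohort, si, occ, ti)
                    p = float(
                        expit(
                            lat.ability_logit
                            - spec.difficulty_logit
                            + config.practice_gain_logit * prior
                            + shift.accuracy_logit_shift
                            + state_logit
                        )
                    )
                    mu = (
                        lat.speed_log
                        + spec.log_rt_offset
                        + config.practice_rt_log * prior
                        + shift.rt_log_shift
                        + state_rt_log
                    )
                    cell = _cell_draws(rng, spec, p, mu, sigma, t0)
                    yield lat, spec, occ, prior, shift, state, cell


def _ground_truth_row(
    lat: SubjectLatents, occ: int, prior: int, shift: DeclineShift, state: tuple[float, float]
) -> dict:
    return {
        "cohort": lat.cohort,
        "subject_id": lat.subject_id,
        "occasion": occ,
        "susceptible": lat.susceptible,
        "ability_logit": lat.ability_logit,
        "speed_log": lat.speed_log,
        "prior_attempts": prior,
        "rt_log_shift": shift.rt_log_shift,
        "accuracy_logit_shift": shift.accuracy_logit_shift,
        "state_logit": state[0],
        "state_rt_log": state[1],
    }


def simulate_cohort(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate full trial-level data for both cohorts.

    Returns ``(intervention_trials, control_trials, ground_truth)``; the
    ground-truth frame has one row per subject x occasion with the latents
    and the shifts actually applied (identically zero for controls).
    """
    cols: dict[str, dict[str, list]] = {
        c: {k: [] for k in TRIAL_COLUMNS + ["stimulus"]} for c in ("intervention", "control")
    }
    truth_rows: list[dict] = []
    seen: set[tuple[str, int]] = set()
    for lat, spec, occ, prior, shift, state, cell in _iter_cells(config):
        stimulus, kind, scorable, correct, rt = cell
        n = spec.n_trials
        acc = cols[lat.cohort]
        acc["subject_id"].append(np.repeat(lat.subject_id, n))
        acc["cohort"].append(np.repeat(lat.cohort, n))
        acc["occasion"].append(np.repeat(occ, n))
        acc["test_id"].append(np.repeat(spec.test_id, n))
        acc["trial_index"].append(np.arange(n))
        acc["stimulus_kind"].append(kind)
        acc["scorable"].append(scorable)
        acc["response_correct"].append(correct)
        acc["rt_seconds"].append(rt)
        acc["stimulus"].append(stimulus)
        key = (lat.subject_id, occ)
        if key not in seen:
            seen.add(key)
            truth_rows.append(_ground_truth_row(lat, occ, prior, shift, state))

    def _assemble(acc: dict[str, list]) -> pd.DataFrame:
        return pd.DataFrame({k: np.concatenate(v) for k, v in acc.items()})

    intervention = _assemble(cols["intervention"])
    control = _assemble(cols["control"])
    truth = pd.DataFrame(truth_rows)
    return intervention, control, truth


def simulate_scores(
    config: ScenarioConfig, rt_rule: str = "correct_only"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell scores directly, without materialising trials.

    Consumes exactly the same random stream as :func:`simulate_cohort` and
    aggregates each cell the way :func:`cogdecline.scoring.score_battery`
    would, so the two routes agree to floating-point round-off.  Intended
    for large calibration runs.
    """
    if rt_rule not in ("correct_only", "all_scorable"):
        raise ConfigurationError(f"unknown rt_rule {rt_rule!r}")
    rows: dict[str, list[dict]] = {"intervention": [], "control": []}
    truth_rows: list[dict] = []
    seen: set[tuple[str, int]] = set()
    for lat, spec, occ, prior, shift, state, cell in _iter_cells(config):
        stimulus, kind, scorable, correct, rt = cell
        n_scorable = int(scorable.sum())
        if n_scorable == 0:
            raise ScoringError(
                f"no scorable trials for ({lat.subject_id}, {occ}, {spec.test_id})"
            )
        acc = float(correct[scorable].mean())
        if rt_rule == "correct_only":
            sel = scorable & correct
            if not sel.any():
                raise ScoringError(
                    f"no correct scorable trials for ({lat.subject_id}, {occ}, "
                    f"{spec.test_id}) under rt_rule='correct_only'"
                )
        else:
            sel = scorable
        rows[lat.cohort].append(
            {
                "subject_id": lat.subject_id,
                "cohort": lat.cohort,
                "occasion": occ,
                "test_id": spec.test_id,
                "accuracy": acc,
                "mean_rt": float(rt[sel].mean()),
                "n_scorable": n_scorable,
            }
        )
        key = (lat.subject_id, occ)
        if key not in seen:
            seen.add(key)
            truth_rows.append(_ground_truth_row(lat, occ, prior, shift, state))

    def _frame(recs: list[dict]) -> pd.DataFrame:
        df = pd.DataFrame(recs)
        return df.sort_values(["subject_id", "occasion", "test_id"], ignore_index=True)

    return _frame(rows["intervention"]), _frame(rows["control"]), pd.DataFrame(truth_rows)
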