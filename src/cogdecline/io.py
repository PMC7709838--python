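"""CSV schemas, readers/writers and scenario-configuration loading.

All artifacts are plain UTF-8 CSV with a mandatory header row and "." as
the decimal separator; readers validate both schema (column presence and
order-insensitive types) and row-level constraints, reporting the file
line number and column of the first violation.  Writers emit columns in a
fixed order so that identical tables serialise byte-identically.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .cohort import DeclineShift, ScenarioConfig, TRIAL_COLUMNS
from .exceptions import ValidationError
from .learning import LEARNING_COLUMNS
from .rci import CLASSIFICATION_COLUMNS, SUMMARY_COLUMNS, Z_COLUMNS
from .schedule import Occasion, TimepointSchedule, make_schedule
from .scoring import CHANGE_COLUMNS, SCORE_COLUMNS
from .tasks import KINDS_BY_TEST, TEST_IDS, TestSpec

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(column: str):
    def parse(s: pd.Series) -> pd.Series:
        lowered = s.astype(str).str.strip().str.lower()
        bad = ~lowered.isin(_BOOL_MAP)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"line {row + 2}, column '{column}': not a boolean ({s.iloc[row]!r})"
            )
        return lowered.map(_BOOL_MAP)

    return parse


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df[columns]


def _coerce(df: pd.DataFrame, column: str, dtype, check: Callable | None = None, what: str = ""):
    try:
        values = df[column].astype(dtype)
    except (TypeError, ValueError) as exc:
        bad_row = 0
        for i, v in enumerate(df[column]):
            try:
                dtype(v)
            except (TypeError, ValueError):
                bad_row = i
                break
        raise ValidationError(
            f"line {bad_row + 2}, column '{column}': cannot parse {df[column].iloc[bad_row]!r}"
        ) from exc
    if check is not None:
        bad = ~values.map(check)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"line {row + 2}, column '{column}': {values.iloc[row]!r} {what}"
            )
    return values


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-level CSV."""
    df = _read_csv(path, TRIAL_COLUMNS)
    if len(df) == 0:
        return df.astype(
            {"occasion": int, "trial_index": int, "rt_seconds": float}
        ).assign(scorable=pd.Series(dtype=bool), response_correct=pd.Series(dtype=bool))
    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "cohort": _coerce(
                df, "cohort", str, lambda v: v in ("intervention", "control"), "is not a cohort"
            ),
            "occasion": _coerce(df, "occasion", int, lambda v: v >= 1, "must be >= 1"),
            "test_id": _coerce(df, "test_id", str, lambda v: v in TEST_IDS, "is not a test id"),
            "trial_index": _coerce(df, "trial_index", int, lambda v: v >= 0, "must be >= 0"),
            "stimulus_kind": df["stimulus_kind"],
            "scorable": _parse_bool("scorable")(df["scorable"]),
            "response_correct": _parse_bool("response_correct")(df["response_correct"]),
            "rt_seconds": _coerce(df, "rt_seconds", float, lambda v: v > 0, "must be positive"),
        }
    )
    kinds_ok = [
        k in KINDS_BY_TEST[t] for k, t in zip(out["stimulus_kind"], out["test_id"])
    ]
    if not all(kinds_ok):
        row = kinds_ok.index(False)
        raise ValidationError(
            f"line {row + 2}, column 'stimulus_kind': {out['stimulus_kind'].iloc[row]!r} "
            f"inconsistent with test {out['test_id'].iloc[row]!r}"
        )
    return out


def write_trials(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = _read_csv(path, SCORE_COLUMNS)
    if len(df) == 0:
        return df.astype({"occasion": int, "accuracy": float, "mean_rt": float, "n_scorable": int})
    return pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "cohort": df["cohort"],
            "occasion": _coerce(df, "occasion", int, lambda v: v >= 1, "must be >= 1"),
            "test_id": _coerce(df, "test_id", str, lambda v: v in TEST_IDS, "is not a test id"),
            "accuracy": _coerce(
                df, "accuracy", float, lambda v: 0.0 <= v <= 1.0, "must lie in [0, 1]"
            ),
            "mean_rt": _coerce(df, "mean_rt", float, lambda v: v > 0, "must be positive"),
            "n_scorable": _coerce(df, "n_scorable", int, lambda v: v >= 1, "must be >= 1"),
        }
    )


def write_scores(df: pd.DataFrame, path) -> None:
    df[SCORE_COLUMNS].to_csv(path, index=False)


def read_changes(path) -> pd.DataFrame:
    df = _read_csv(path, CHANGE_COLUMNS)
    if len(df) == 0:
        return df.astype({"occasion": int, "delta": float})
    return pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "occasion": _coerce(df, "occasion", int, lambda v: v >= 2, "must be >= 2"),
            "test_id": _coerce(df, "test_id", str, lambda v: v in TEST_IDS, "is not a test id"),
            "metric": _coerce(
                df, "metric", str, lambda v: v in ("accuracy", "rt"), "is not a metric"
            ),
            "delta": _coerce(df, "delta", float, np.isfinite, "must be finite"),
        }
    )


def write_changes(df: pd.DataFrame, path) -> None:
    df[CHANGE_COLUMNS].to_csv(path, index=False)


def read_learning(path) -> pd.DataFrame:
    df = _read_csv(path, LEARNING_COLUMNS)
    if len(df) == 0:
        return df.astype({"mean_change": float, "sd_change": float, "n_control": int})
    return pd.DataFrame(
        {
            "test_id": _coerce(df, "test_id", str, lambda v: v in TEST_IDS, "is not a test id"),
            "metric": _coerce(
                df, "metric", str, lambda v: v in ("accuracy", "rt"), "is not a metric"
            ),
            "mean_change": _coerce(df, "mean_change", float, np.isfinite, "must be finite"),
            "sd_change": _coerce(df, "sd_change", float, lambda v: v >= 0, "must be >= 0"),
            "n_control": _coerce(df, "n_control", int, lambda v: v >= 2, "must be >= 2"),
        }
    )


def write_learning(df: pd.DataFrame, path) -> None:
    df[LEARNING_COLUMNS].to_csv(path, index=False)


def write_z_scores(df: pd.DataFrame, path) -> None:
    df[Z_COLUMNS].to_csv(path, index=False)


def write_classifications(df: pd.DataFrame, path) -> None:
    df[CLASSIFICATION_COLUMNS].to_csv(path, index=False)


def write_summary(df: pd.DataFrame, path) -> None:
    df[SUMMARY_COLUMNS].to_csv(path, index=False)


def write_ground_truth(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scenario configuration (YAML / JSON)
# ---------------------------------------------------------------------------


def scenario_to_dict(config: ScenarioConfig) -> dict:
    """Plain-dict form of a scenario, round-trippable through YAML/JSON."""
    return {
        "n_intervention": config.n_intervention,
        "n_control": config.n_control,
        "schedule": [
            {
                "index": o.index,
                "label": o.label,
                "position": o.position,
                "minutes_from_start": o.minutes_from_start,
            }
            for o in config.schedule
        ],
        "test_specs": [
            {
                "test_id": t.test_id,
                "n_trials": t.n_trials,
                "target_rate": t.target_rate,
                "incongruent_fraction": t.incongruent_fraction,
                "nonword_fraction": t.nonword_fraction,
                "difficulty_logit": t.difficulty_logit,
                "log_rt_offset": t.log_rt_offset,
            }
            for t in config.test_specs
        ],
        "practice_gain_logit": config.practice_gain_logit,
        "practice_rt_log": config.practice_rt_log,
        "decline_profile": {
            str(k): {"rt_log_shift": v.rt_log_shift, "accuracy_logit_shift": v.accuracy_logit_shift}
            for k, v in sorted(config.decline_profile.items())
        },
        "susceptible_fraction": config.susceptible_fraction,
        "susceptibility_multiplier": config.susceptibility_multiplier,
        "ability_mean_logit": config.ability_mean_logit,
        "speed_mean_log": config.speed_mean_log,
        "subject_sd_logit": config.subject_sd_logit,
        "subject_sd_rt_log": config.subject_sd_rt_log,
        "rt_sigma_log": config.rt_sigma_log,
        "rt_shift_seconds": config.rt_shift_seconds,
        "n_control_attempts": config.n_control_attempts,
        "practice_runs_before_baseline": config.practice_runs_before_baseline,
        "seed": config.seed,
    }


def scenario_from_dict(data: dict) -> ScenarioConfig:
    data = dict(data)
    schedule = data.pop("schedule", None)
    if schedule is None:
        sched = make_schedule()
    elif isinstance(schedule, dict):
        sched = make_schedule(**schedule)
    else:
        sched = TimepointSchedule(
            tuple(
                Occasion(
                    int(o["index"]), o["label"], o["position"], float(o["minutes_from_start"])
                )
                for o in schedule
            )
        )
    specs = data.pop("test_specs", None)
    test_specs = (
        tuple(TestSpec(**s) for s in specs) if specs is not None else None
    )
    profile = data.pop("decline_profile", None)
    kwargs = dict(data)
    kwargs["schedule"] = sched
    if test_specs is not None:
        kwargs["test_specs"] = test_specs
    if profile is not None:
        kwargs["decline_profile"] = {
            int(k): DeclineShift(
                float(v.get("rt_log_shift", 0.0)), float(v.get("accuracy_logit_shift", 0.0))
            )
            if isinstance(v, dict)
            else DeclineShift(*v)
            for k, v in profile.items()
        }
    try:
        return ScenarioConfig(**kwargs)
    except TypeError as exc:
        raise ValidationError(f"bad scenario config: {exc}") from exc


def load_scenario(path) -> ScenarioConfig:
    """Load a scenario configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return scenario_from_dict(data)


def save_scenario(config: ScenarioConfig, path) -> None:
    path = Path(path)
    data = scenario_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
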