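"""End-to-end pipeline: simulate/ingest -> score -> learning effect ->
classify -> summarise -> repeated-measures analysis -> markdown report.

Every stage communicates through CSV files in the output directory, so a
run is inspectable and restartable; a JSON manifest records the config
hash, seed, package version and the per-stage outputs with content hashes.
Rerunning with an identical configuration and seed reproduces every output
byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io as cio
from .cohort import ScenarioConfig, simulate_cohort
from .exceptions import PipelineStageError, ValidationError
from .group import RMAnovaResult
from .rci import ClassificationRule, ReliableChangeModel, round_half_up
from .schedule import TimepointSchedule

logger = logging.getLogger("cogdecline")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Provide either a generative ``scenario`` or paths to existing trial CSVs
    (``trials_path`` + ``control_trials_path``); exactly one input source is
    required.
    """

    out_dir: str | Path
    scenario: ScenarioConfig | None = None
    trials_path: str | Path | None = None
    control_trials_path: str | Path | None = None
    rt_rule: str = "correct_only"
    rule: ClassificationRule = field(default_factory=ClassificationRule)
    conf_level: float = 0.95
    seed: int | None = None
    schedule: TimepointSchedule | None = None

    def __post_init__(self) -> None:
        have_scenario = self.scenario is not None
        have_files = self.trials_path is not None
        if have_scenario == have_files:
            raise ValidationError(
                "provide exactly one of: a scenario, or trial CSV paths"
            )
        if have_files and self.control_trials_path is None:
            raise ValidationError("control_trials_path required with trials_path")
        if self.scenario is not None and self.seed is not None:
            self.scenario = dataclasses.replace(self.scenario, seed=int(self.seed))


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    version: str
    outputs: dict[str, dict]
    status: str
    failed_stage: str | None
    started: str
    finished: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_digest(config: PipelineConfig) -> str:
    payload = {
        "scenario": cio.scenario_to_dict(config.scenario) if config.scenario else None,
        "trials_path": str(config.trials_path) if config.trials_path else None,
        "control_trials_path": (
            str(config.control_trials_path) if config.control_trials_path else None
        ),
        "rt_rule": config.rt_rule,
        "rule": dataclasses.asdict(config.rule),
        "conf_level": config.conf_level,
        "seed": config.seed,
    }
    blob = json.dumps(payload, sort_keys=True, default=repr).encode()
    return hashlib.sha256(blob).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    cols = list(df.columns)
    fmt = lambda v: floatfmt.format(v) if isinstance(v, float) else str(v)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def _render_report(results, schedule: TimepointSchedule | None, manifest_info: dict) -> str:
    summary = results.timepoint_summary.copy()
    summary["pct_decline"] = summary["pct_decline"].map(round_half_up)
    parts = [
        "# Reliable-change pipeline report",
        "",
        f"Config hash `{manifest_info['config_hash'][:12]}`, seed "
        f"{manifest_info['seed']}, cogdecline {manifest_info['version']}.",
        "",
        "## Subjects with cognitive decline by occasion",
        "",
        "Counts of subjects whose practice-corrected change from their own "
        "baseline crossed the reliable-change threshold (percentages rounded "
        "to the nearest integer).",
        "",
        _md_table(summary),
        "",
        "## Practice (learning) effects from the control cohort",
        "",
        _md_table(results.learning_effects),
        "",
    ]
    for metric, title in (("accuracy", "Accuracy"), ("rt", "Response time")):
        part = results.change_summaries[results.change_summaries["metric"] == metric]
        a: RMAnovaResult = results.anova[metric]
        parts += [
            f"## {title}: mean change from baseline",
            "",
            f"Repeated-measures ANOVA across occasions: "
            f"F({a.df1:g}, {a.df2:g}) = {a.f_value:.3f}, p = {a.p_value:.4g}.",
            "",
            _md_table(part.drop(columns=["metric"])),
            "",
        ]
    return "\n".join(parts)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline, writing CSVs, a report and a manifest.

    Stage errors are wrapped in :class:`PipelineStageError` naming the
    failing stage; a manifest flagging the failure is written before the
    error propagates.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    digest = _config_digest(config)
    outputs: dict[str, dict] = {}
    seed = config.seed if config.seed is not None else (
        config.scenario.seed if config.scenario else None
    )
    info = {"config_hash": digest, "seed": seed, "version": __version__}

    def record(stage: str, path: Path) -> None:
        outputs.setdefault(stage, {})[path.name] = _file_hash(path)

    current_stage = "setup"
    try:
        schedule = config.schedule
        if config.scenario is not None:
            current_stage = "simulate"
            logger.info("[simulate] generating synthetic cohort (seed=%s)", seed)
            trials, control_trials, truth = simulate_cohort(config.scenario)
            schedule = config.scenario.schedule
            for name, df in (
                ("trials_intervention.csv", trials),
                ("trials_control.csv", control_trials),
            ):
                cio.write_trials(df, out_dir / name)
                record("simulate", out_dir / name)
            cio.write_ground_truth(truth, out_dir / "ground_truth.csv")
            record("simulate", out_dir / "ground_truth.csv")
        else:
            current_stage = "ingest"
            logger.info("[ingest] reading trial CSVs")
            trials = cio.read_trials(config.trials_path)
            control_trials = cio.read_trials(config.control_trials_path)
            if len(trials) == 0 or len(control_trials) == 0:
                raise ValidationError("trial tables must be non-empty")

        current_stage = "score"
        logger.info("[score] reducing trials to per-cell scores (%s)", config.rt_rule)
        from .scoring import change_from_baseline, score_battery

        scores = score_battery(trials, rt_rule=config.rt_rule)
        control_scores = score_battery(control_trials, rt_rule=config.rt_rule)
        cio.write_scores(scores, out_dir / "scores_intervention.csv")
        cio.write_scores(control_scores, out_dir / "scores_control.csv")
        record("score", out_dir / "scores_intervention.csv")
        record("score", out_dir / "scores_control.csv")
        changes = change_from_baseline(scores)
        cio.write_changes(changes, out_dir / "changes.csv")
        record("score", out_dir / "changes.csv")

        current_stage = "analyse"
        logger.info("[analyse] fitting reliable-change model")
        model = ReliableChangeModel(
            scores,
            control_scores,
            schedule=schedule,
            rule=config.rule,
            conf_level=config.conf_level,
        )
        results = model.fit()
        cio.write_learning(results.learning_effects, out_dir / "learning.csv")
        cio.write_z_scores(results.z_scores, out_dir / "z_scores.csv")
        cio.write_classifications(results.classifications, out_dir / "classifications.csv")
        cio.write_summary(results.timepoint_summary, out_dir / "timepoint_summary.csv")
        results.change_summaries.to_csv(out_dir / "change_summaries.csv", index=False)
        anova_df = pd.DataFrame(
            [{"metric": m, **dataclasses.asdict(a)} for m, a in results.anova.items()]
        )
        anova_df.to_csv(out_dir / "rm_anova.csv", index=False)
        for name in (
            "learning.csv",
            "z_scores.csv",
            "classifications.csv",
            "timepoint_summary.csv",
            "change_summaries.csv",
            "rm_anova.csv",
        ):
            record("analyse", out_dir / name)

        current_stage = "report"
        logger.info("[report] rendering markdown report")
        (out_dir / "report.md").write_text(_render_report(results, schedule, info), encoding="utf-8")
        record("report", out_dir / "report.md")
    except PipelineStageError:
        raise
    except Exception as exc:
        manifest = RunManifest(
            digest, seed, __version__, outputs, "failed", current_stage, started,
            time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2), encoding="utf-8"
        )
        raise PipelineStageError(current_stage, str(exc)) from exc

    manifest = RunManifest(
        digest, seed, __version__, outputs, "ok", None, started,
        time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2), encoding="utf-8"
    )
    logger.info("[done] %d files in %s", sum(len(v) for v in outputs.values()), out_dir)
    return manifest
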