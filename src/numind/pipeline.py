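"""Configuration, deterministic seeding, readers/writers and the full pipeline.

One master seed fans out, through named ``numpy.random.SeedSequence``
children taken in a fixed order (design, engine, synth, fit), into
per-stage seeds, so any stage can be rerun in isolation and the whole
pipeline is byte-reproducible.

File formats are plain text: BIDS-events-style TSV for trials, a TSV of
(module, onset, duration, label) rows for traces, CSV for BOLD timecourses
and behavioral summaries, JSON for the fit report.  All floats are written
with ``repr`` so that read(write(x)) round-trips exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bold as bold_mod
from .analysis import fit_parameters, summarize_behavior
from .bold import HRFParams, block_bold
from .cogmodel import (EngineParams, ExperimentResult, TraceEvent,
                       run_experiment)
from .stimuli import (CONDITIONS, DesignParams, RunDesign, StimulusConfig)
from .synthetic_data import ParticipantSpec

log = logging.getLogger("numind")

STAGES = ("design", "engine", "synth", "fit")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class ParseError(ValueError):
    """Malformed record in a numind-produced file."""


@dataclass
class PipelineConfig:
    seed: int = 0
    n_runs: int = 2
    tr: float = 2.0
    engine: EngineParams = field(default_factory=EngineParams)
    hrf: HRFParams = field(default_factory=HRFParams)
    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    design: DesignParams = field(default_factory=DesignParams)
    participants: ParticipantSpec = field(default_factory=ParticipantSpec)
    fit_grid: dict = field(default_factory=lambda: {
        "latency_factor": [0.3, 0.35, 0.4, 0.45, 0.5],
        "problem_state_dt": [0.3, 0.35, 0.4, 0.45, 0.5],
    })
    run_fit: bool = False


def _build_section(cls, data: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown key '{section}.{key}'")
        if isinstance(value, list) and isinstance(fields[key].default, tuple):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config, rejecting unknown keys by name."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    sections = {"engine": EngineParams, "hrf": HRFParams,
                "stimuli": StimulusConfig, "design": DesignParams,
                "participants": ParticipantSpec}
    kwargs = {}
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, value in data.items():
        if key not in top_fields:
            raise ConfigError(f"unknown key '{key}'")
        if key in sections:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(sections[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one independent 31-bit seed per pipeline stage."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("onset", "duration", "trial_type", "stimulus", "response",
                 "response_time", "accuracy")
TRACE_COLUMNS = ("module", "onset", "duration", "label")


def events_table(experiment: ExperimentResult, run_index: int = 0) -> list[dict]:
    """Flatten one run's trials into BIDS-events-style rows (onset 0 at
    run start)."""
    rows = []
    blocks = [b for b in experiment.blocks if b.run_index == run_index]
    for bi, block in enumerate(blocks):
        d = block.design
        block_t0 = bi * (d.cue_duration + d.task_duration + d.rest_duration)
        for trial in block.trials:
            rows.append({
                "onset": block_t0 + trial.onset,
                "duration": trial.rt,
                "trial_type": block.condition,
                "stimulus": trial.stimulus.text(),
                "response": "timeout" if trial.timed_out
                else trial.stimulus.correct_side if trial.correct
                else ("right" if trial.stimulus.correct_side == "left"
                      else "left"),
                "response_time": trial.rt,
                "accuracy": int(trial.correct),
            })
    return rows


def write_events(path: str | Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVENT_COLUMNS)
        for row in rows:
            w.writerow([repr(float(row["onset"])),
                        repr(float(row["duration"])),
                        row["trial_type"], row["stimulus"], row["response"],
                        repr(float(row["response_time"])),
                        int(row["accuracy"])])


def read_events(path: str | Path) -> list[dict]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != list(EVENT_COLUMNS):
            raise ParseError(f"{path}: line 1: bad header {header}")
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != len(EVENT_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: expected "
                                 f"{len(EVENT_COLUMNS)} fields, got {len(rec)}")
            try:
                rows.append({
                    "onset": float(rec[0]), "duration": float(rec[1]),
                    "trial_type": rec[2], "stimulus": rec[3],
                    "response": rec[4], "response_time": float(rec[5]),
                    "accuracy": int(rec[6]),
                })
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def write_trace(path: str | Path, trace: list[TraceEvent]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRACE_COLUMNS)
        for e in trace:
            w.writerow([e.module, repr(float(e.onset)),
                        repr(float(e.duration)), e.label])


def read_trace(path: str | Path) -> list[TraceEvent]:
    events = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != list(TRACE_COLUMNS):
            raise ParseError(f"{path}: line 1: bad header {header}")
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 fields")
            try:
                events.append(TraceEvent(rec[0], float(rec[1]),
                                         float(rec[2]), rec[3]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return events


BOLD_COLUMNS = ("time_s", "value", "kind", "module", "condition")


def write_bold(path: str | Path, df: pd.DataFrame) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(BOLD_COLUMNS)
        for rec in df.itertuples(index=False):
            w.writerow([repr(float(rec.time_s)), repr(float(rec.value)),
                        rec.kind, rec.module, rec.condition])


def read_bold(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != list(BOLD_COLUMNS):
            raise ParseError(f"{path}: line 1: bad header {header}")
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 fields")
            try:
                rows.append({"time_s": float(rec[0]), "value": float(rec[1]),
                             "kind": rec[2], "module": rec[3],
                             "condition": rec[4]})
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=list(BOLD_COLUMNS))


def write_design(path: str | Path, runs: list[RunDesign]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["run", "block", "condition", "position", "stimulus",
                    "correct_answer"])
        for run in runs:
            for bi, block in enumerate(run.blocks):
                for pos, stim in enumerate(block.stimulus_pool):
                    w.writerow([run.run_index, bi, block.condition, pos,
                                stim.text(), stim.correct_answer])


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute generate -> simulate -> predict-bold -> analyze.

    Writes designs, per-run events, the merged trace, condition BOLD
    timecourses, behavioral and AUC summaries (plus a fit report when
    ``run_fit`` is set) into *outdir* and returns the paths.  Deterministic:
    the same config always produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    log.info("pipeline start: seed=%d stage_seeds=%s", config.seed, seeds)

    engine = replace(config.engine, activation=dict(config.engine.activation))
    exp = run_experiment(engine, n_runs=config.n_runs, seed=seeds["design"],
                         stim_config=config.stimuli, design=config.design)
    paths: dict[str, Path] = {}

    from .stimuli import build_runs  # design rebuilt for the design file
    runs = build_runs(np.random.default_rng(
        np.random.SeedSequence(seeds["design"]).spawn(2)[0]),
        n_runs=config.n_runs, config=config.stimuli, design=config.design)
    paths["design"] = outdir / "design.tsv"
    write_design(paths["design"], runs)

    for r in range(config.n_runs):
        p = outdir / f"events_run-{r + 1}.tsv"
        write_events(p, events_table(exp, run_index=r))
        paths[f"events_run{r + 1}"] = p
    block_len = (config.design.cue_duration + config.design.task_duration
                 + config.design.rest_duration)
    for r in range(config.n_runs):
        run_blocks = [b for b in exp.blocks if b.run_index == r]
        merged = [replace_onset(e, bi * block_len)
                  for bi, b in enumerate(run_blocks) for e in b.trace]
        p = outdir / f"trace_run-{r + 1}.tsv"
        write_trace(p, merged)
        paths[f"trace_run{r + 1}"] = p

    summary = summarize_behavior(exp)
    paths["behavior"] = outdir / "behavior_summary.csv"
    summary.to_csv(paths["behavior"], float_format="%.6f")

    bold_rows = []
    auc_rows = []
    for module in ("declarative", "problem_state"):
        for cond in CONDITIONS:
            blocks = exp.blocks_of(cond)
            curves = []
            aucs = []
            for block in blocks:
                raw, pct = block_bold(block, module, config.hrf, tr=config.tr)
                curves.append(pct.values)
                d = block.design
                aucs.append(bold_mod.auc(
                    pct, (d.cue_duration, d.cue_duration + d.task_duration)))
            mean_curve = np.mean(curves, axis=0)
            t0 = -bold_mod.N_PRE_SCANS * config.tr
            for i, v in enumerate(mean_curve):
                bold_rows.append({"time_s": t0 + i * config.tr,
                                  "value": float(v), "kind": "percent_change",
                                  "module": module, "condition": cond})
            auc_rows.append({"module": module, "condition": cond,
                             "auc_mean": float(np.mean(aucs))})
    paths["bold"] = outdir / "bold_timecourses.csv"
    write_bold(paths["bold"], pd.DataFrame(bold_rows))
    paths["auc"] = outdir / "auc_summary.csv"
    pd.DataFrame(auc_rows).to_csv(paths["auc"], index=False,
                                  float_format="%.6f")

    if config.run_fit:
        fit = fit_parameters(summary, config.fit_grid, seed=seeds["fit"],
                             base_params=engine, stim_config=config.stimuli)
        paths["fit"] = outdir / "fit_report.json"
        with open(paths["fit"], "w") as fh:
            json.dump({"latency_factor": fit.latency_factor,
                       "problem_state_dt": fit.problem_state_dt,
                       "loss": fit.loss}, fh, indent=2, sort_keys=True)
    log.info("pipeline done: %d artifacts in %s", len(paths), outdir)
    return paths


def replace_onset(e: TraceEvent, offset: float) -> TraceEvent:
    return TraceEvent(e.module, e.onset + offset, e.duration, e.label)
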