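"""Virtual-participant datasets with known ground truth.

The study's raw data are not deposited, so every downstream stage is
exercised on synthetic cohorts instead: each of 15 virtual subjects is one
full model run (2 runs x 9 blocks) degraded by three independent noise
sources —

* subject-level RT jitter: one lognormal multiplicative factor per subject
  (positive support, median 1);
* response flips: each trial's correctness flips with a small probability;
* scan noise: white Gaussian noise (signal units) added to the raw BOLD
  series before the percent-change step.

All subjects see the same stimulus design (as in the real study); with all
noise terms at zero every subject reproduces the deterministic model mean
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import bold as bold_mod
from .analysis import fit_parameters, summarize_behavior
from .bold import HRFParams, block_bold, auc as bold_auc
from .cogmodel import EngineParams, ExperimentResult, run_design
from .stimuli import CONDITIONS, DEFAULT_STIM_CONFIG, StimulusConfig, build_runs

#: the two ROI-mapped modules analyzed in the study
ROI_MODULES = ("declarative", "problem_state")


@dataclass(frozen=True)
class ParticipantSpec:
    """Cohort size and noise levels for a synthetic dataset."""

    n_subjects: int = 15
    rt_noise_sd: float = 0.10      # lognormal sigma of the subject RT factor
    accuracy_flip_prob: float = 0.02
    bold_noise_sd: float = 0.05    # signal units, on raw BOLD scans
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.accuracy_flip_prob <= 1:
            raise ValueError("accuracy_flip_prob must be in [0, 1]")
        if self.rt_noise_sd < 0 or self.bold_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")


@dataclass
class ParticipantDataset:
    """Behavioral table, per-subject AUC tables and mean BOLD curves."""

    behavior: pd.DataFrame              # subject x condition summaries, long
    auc: dict[str, pd.DataFrame]        # module -> subjects x conditions
    bold: pd.DataFrame                  # subject, module, condition, t, value
    spec: ParticipantSpec

    def behavior_targets(self) -> pd.DataFrame:
        """Across-subject mean summary, usable as fitting targets."""
        return (self.behavior.groupby("condition")
                [["mean_rt", "accuracy", "trials_mean"]].mean()
                .reindex([c for c in CONDITIONS]))


def _apply_behavior_noise(exp: ExperimentResult, rt_factor: float,
                          flip_prob: float, rng: np.random.Generator) -> None:
    for block in exp.blocks:
        for trial in block.trials:
            if not trial.timed_out:
                trial.rt *= rt_factor
            if flip_prob > 0 and rng.random() < flip_prob:
                trial.correct = not trial.correct


def simulate_participants(
    true_params: EngineParams | None = None,
    hrf: HRFParams = HRFParams(),
    spec: ParticipantSpec = ParticipantSpec(),
    stim_config: StimulusConfig = DEFAULT_STIM_CONFIG,
    n_runs: int = 2,
    modules: tuple[str, ...] = ROI_MODULES,
    compute_bold: bool = True,
) -> ParticipantDataset:
    """Simulate a cohort of virtual participants.

    Each subject re-runs the engine (own activation-noise stream) on a
    design shared across the cohort, then receives subject-level RT jitter,
    response flips and additive scan noise.  AUC tables are per module,
    subjects x conditions, averaged over each condition's blocks.
    """
    spec.validate()
    params = EngineParams() if true_params is None else true_params
    ss = np.random.SeedSequence(spec.seed)
    design_ss, *subject_ss = ss.spawn(1 + spec.n_subjects)
    runs = build_runs(np.random.default_rng(design_ss), n_runs=n_runs,
                      config=stim_config)

    behavior_rows = []
    auc_rows: dict[str, list[dict]] = {m: [] for m in modules}
    bold_rows = []
    for subj, sub_ss in enumerate(subject_ss):
        engine_rng, noise_rng, scan_rng = (np.random.default_rng(s)
                                           for s in sub_ss.spawn(3))
        exp = run_design(runs, params, engine_rng)
        rt_factor = (float(np.exp(noise_rng.normal(0.0, spec.rt_noise_sd)))
                     if spec.rt_noise_sd > 0 else 1.0)
        _apply_behavior_noise(exp, rt_factor, spec.accuracy_flip_prob,
                              noise_rng)
        summary = summarize_behavior(exp)
        for cond, row in summary.iterrows():
            behavior_rows.append({"subject": subj, "condition": cond,
                                  **row.to_dict()})
        if not compute_bold:
            continue
        for module in modules:
            per_cond_auc: dict[str, list[float]] = {}
            per_cond_pct: dict[str, list[np.ndarray]] = {}
            for block in exp.blocks:
                raw, pct = block_bold(
                    block, module, hrf,
                    noise_sd=spec.bold_noise_sd,
                    rng=scan_rng if spec.bold_noise_sd > 0 else None)
                d = block.design
                a = bold_auc(pct, (d.cue_duration,
                                   d.cue_duration + d.task_duration))
                per_cond_auc.setdefault(block.condition, []).append(a)
                per_cond_pct.setdefault(block.condition, []).append(pct.values)
            row = {"subject": subj}
            for cond, vals in per_cond_auc.items():
                row[cond] = float(np.mean(vals))
            auc_rows[module].append(row)
            for cond, curves in per_cond_pct.items():
                mean_curve = np.mean(curves, axis=0)
                t0 = -bold_mod.N_PRE_SCANS * bold_mod.TR
                for i, v in enumerate(mean_curve):
                    bold_rows.append({"subject": subj, "module": module,
                                      "condition": cond,
                                      "t": t0 + i * bold_mod.TR,
                                      "value": float(v)})

    behavior = pd.DataFrame(behavior_rows)
    auc_tables = {
        m: pd.DataFrame(rows).set_index("subject")[list(CONDITIONS)]
        for m, rows in auc_rows.items() if rows
    }
    bold_df = pd.DataFrame(
        bold_rows, columns=["subject", "module", "condition", "t", "value"])
    return ParticipantDataset(behavior=behavior, auc=auc_tables,
                              bold=bold_df, spec=spec)


def recovery_harness(
    grid: dict[str, list[float]],
    spec: ParticipantSpec = ParticipantSpec(),
    n_replicates: int = 20,
    seed: int = 0,
    base_params: EngineParams | None = None,
    fit_experiments: int = 2,
    stim_config: StimulusConfig = DEFAULT_STIM_CONFIG,
) -> pd.DataFrame:
    """Simulate-and-refit loop quantifying parameter recovery.

    For each replicate a true (latency factor, problem-state duration) pair
    is drawn from the grid, a synthetic cohort is generated at those values,
    and :func:`fit_parameters` is run on the cohort's mean behavior.  The
    report has one row per replicate with the true and estimated values and
    the absolute error expressed in grid steps.
    """
    f_values = sorted(grid["latency_factor"])
    dt_values = sorted(grid["problem_state_dt"])
    f_step = min(np.diff(f_values)) if len(f_values) > 1 else 1.0
    dt_step = min(np.diff(dt_values)) if len(dt_values) > 1 else 1.0
    base = EngineParams() if base_params is None else base_params
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        true_f = float(rng.choice(f_values))
        true_dt = float(rng.choice(dt_values))
        true = replace(base, latency_factor=true_f, problem_state_dt=true_dt,
                       activation=dict(base.activation))
        rep_spec = replace(spec, seed=int(rng.integers(2 ** 31)))
        data = simulate_participants(true, spec=rep_spec,
                                     stim_config=stim_config,
                                     compute_bold=False)
        fit = fit_parameters(data.behavior_targets(), grid,
                             seed=int(rng.integers(2 ** 31)),
                             base_params=base,
                             n_experiments=fit_experiments,
                             stim_config=stim_config)
        rows.append({
            "replicate": rep,
            "true_latency_factor": true_f,
            "true_problem_state_dt": true_dt,
            "est_latency_factor": fit.latency_factor,
            "est_problem_state_dt": fit.problem_state_dt,
            "err_latency_steps": abs(fit.latency_factor - true_f) / f_step,
            "err_problem_state_steps": abs(fit.problem_state_dt - true_dt)
            / dt_step,
            "loss": fit.loss,
        })
    return pd.DataFrame(rows)
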