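"""Behavioral summaries, repeated-measures comparisons, and parameter fitting.

The behavioral summary reports, per condition, the mean RT of completed
non-timed-out trials, accuracy (timed-out trials count as errors) and the
number of trials completed per 30-s block.  Condition effects use the
classic one-way repeated-measures ANOVA with ``(k-1, (k-1)(n-1))`` degrees
of freedom and no sphericity correction, matching the study's ``F(2, 28)``
convention for 15 subjects and 3 conditions.

``fit_parameters`` recovers the two fitted engine parameters (latency
factor and problem-state change duration) by grid search against behavioral
targets, minimizing a squared error over per-condition mean RT and
trials/block after z-scaling each quantity, with common random numbers
across grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .cogmodel import EngineParams, ExperimentResult, run_experiment
from .stimuli import CONDITIONS, DEFAULT_STIM_CONFIG, StimulusConfig

__all__ = [
    "summarize_behavior", "trials_per_block", "repeated_measures_anova",
    "compare_auc", "fit_parameters", "AnovaResult", "AucComparison",
    "FitResult",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float


@dataclass(frozen=True)
class AucComparison:
    F: float
    df: tuple[int, int]
    p: float
    #: sign of mean(a) - mean(b); +1 means the first condition is higher
    direction: int
    higher: str


@dataclass(frozen=True)
class FitResult:
    latency_factor: float
    problem_state_dt: float
    activation_map: dict[str, float]
    loss: float
    grid_losses: pd.DataFrame


def _iter_blocks(results: ExperimentResult | Iterable[ExperimentResult]):
    if isinstance(results, ExperimentResult):
        results = [results]
    for exp in results:
        yield from exp.blocks


def summarize_behavior(
    results: ExperimentResult | Iterable[ExperimentResult],
) -> pd.DataFrame:
    """Per-condition behavioral summary over all blocks of the input.

    Returns a DataFrame indexed by condition with columns ``mean_rt``,
    ``accuracy``, ``trials_mean`` and ``trials_sd``.
    """
    rows = {}
    blocks = list(_iter_blocks(results))
    for cond in CONDITIONS:
        cond_blocks = [b for b in blocks if b.condition == cond]
        if not cond_blocks:
            continue
        trials = [t for b in cond_blocks for t in b.trials]
        if not trials:
            raise ValueError(f"no completed trials in condition {cond}")
        rts = [t.rt for t in trials if not t.timed_out]
        counts = [b.n_completed for b in cond_blocks]
        rows[cond] = {
            "mean_rt": float(np.mean(rts)) if rts else float("nan"),
            "accuracy": float(np.mean([t.correct for t in trials])),
            "trials_mean": float(np.mean(counts)),
            "trials_sd": float(np.std(counts, ddof=1)) if len(counts) > 1
            else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("condition")


def trials_per_block(
    results: ExperimentResult | Iterable[ExperimentResult],
) -> pd.DataFrame:
    """Completed-trial counts per block, long format (condition, count)."""
    recs = [(b.condition, b.n_completed) for b in _iter_blocks(results)]
    return pd.DataFrame(recs, columns=["condition", "n_trials"])


def repeated_measures_anova(table: pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Uses the textbook sum-of-squares partition: condition and subject
    effects removed from the total, the remainder being the error term.
    An all-equal table (zero condition sum of squares) returns ``F = 0``.
    """
    values = np.asarray(table, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D subjects x conditions table")
    if np.isnan(values).any():
        raise ValueError("missing cells in the repeated-measures table")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = values.mean()
    ss_cond = n * float(((values.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((values.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_cond <= 0:
        return AnovaResult(0.0, (df1, df2), 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = ms_cond / ms_err if ms_err > 0 else float("inf")
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), (df1, df2), p)


def compare_auc(table: pd.DataFrame, cond_a: str = "Rea",
                cond_b: str = "Cal") -> AucComparison:
    """Repeated-measures comparison of two conditions' AUC for one ROI.

    ``table`` is subjects x conditions; the two named columns are compared
    with a paired F test (``df = (1, n-1)``) and the direction of the
    ``cond_a - cond_b`` difference is reported.
    """
    sub = table[[cond_a, cond_b]]
    res = repeated_measures_anova(sub)
    diff = float(sub[cond_a].mean() - sub[cond_b].mean())
    direction = int(np.sign(diff))
    higher = {1: cond_a, -1: cond_b, 0: "tie"}[direction]
    return AucComparison(res.F, res.df, res.p, direction, higher)


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

def _simulate_summary(params: EngineParams, seeds: list[int],
                      n_runs: int, stim_config: StimulusConfig) -> pd.DataFrame:
    exps = [run_experiment(params, n_runs=n_runs, seed=s,
                           stim_config=stim_config) for s in seeds]
    return summarize_behavior(exps)


def _target_scales(targets: pd.DataFrame) -> tuple[float, float]:
    s_rt = float(np.std(targets["mean_rt"]))
    s_tpb = float(np.std(targets["trials_mean"]))
    return (s_rt if s_rt > 0 else 1.0), (s_tpb if s_tpb > 0 else 1.0)


def fit_parameters(
    targets: pd.DataFrame,
    grid: dict[str, Iterable[float]],
    seed: int = 0,
    base_params: EngineParams | None = None,
    n_experiments: int = 3,
    n_runs: int = 2,
    stim_config: StimulusConfig = DEFAULT_STIM_CONFIG,
) -> FitResult:
    """Grid-search the latency factor and problem-state change duration.

    *targets* is a behavioral summary (as from :func:`summarize_behavior`)
    with ``mean_rt`` and ``trials_mean`` columns.  The loss is the squared
    error of both quantities per condition, each z-scaled by its spread
    across the target conditions so RT seconds and trial counts weigh
    equally.  Ties break toward the smaller latency factor, then the
    smaller problem-state duration.  The same simulation seeds are reused
    at every grid point (common random numbers), so the fit is
    deterministic given ``seed`` and the grid.
    """
    f_values = sorted(grid.get("latency_factor", []))
    dt_values = sorted(grid.get("problem_state_dt", []))
    if not f_values or not dt_values:
        raise ValueError("grid must contain latency_factor and "
                         "problem_state_dt values")
    base = EngineParams() if base_params is None else base_params
    seeds = [int(c.generate_state(1)[0] % (2 ** 31))
             for c in np.random.SeedSequence(seed).spawn(n_experiments)]
    s_rt, s_tpb = _target_scales(targets)
    conds = [c for c in targets.index if c in CONDITIONS]
    best: tuple[float, float, float] | None = None
    records = []
    for f in f_values:
        for dt in dt_values:
            params = replace(base, latency_factor=f, problem_state_dt=dt,
                             activation=dict(base.activation))
            sim = _simulate_summary(params, seeds, n_runs, stim_config)
            loss = 0.0
            for cond in conds:
                loss += ((sim.loc[cond, "mean_rt"]
                          - targets.loc[cond, "mean_rt"]) / s_rt) ** 2
                loss += ((sim.loc[cond, "trials_mean"]
                          - targets.loc[cond, "trials_mean"]) / s_tpb) ** 2
            records.append({"latency_factor": f, "problem_state_dt": dt,
                            "loss": float(loss)})
            if best is None or loss < best[0]:
                best = (float(loss), f, dt)
    assert best is not None
    loss, f, dt = best
    return FitResult(latency_factor=f, problem_state_dt=dt,
                     activation_map=dict(base.activation), loss=loss,
                     grid_losses=pd.DataFrame.from_records(records))
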