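"""From module traces to predicted ROI BOLD timecourses and AUC statistics.

A module's activity over a block is first discretized into a binary demand
function ``D(t)`` (1 while the module is busy, 0 otherwise) on a fine time
grid, then convolved with a gamma-shaped hemodynamic response

    ``H(t) = m * (t/s)**alpha * exp(-t/s)``

with magnitude ``m``, time scale ``s`` (seconds) and shape ``alpha``.  The
convolution is sampled at the scanner TR (2 s).  Percent signal change uses
the study's baseline: the mean of the 7 rest scans before block onset and
the 8 rest scans after the task ends.  The summary statistic is the
trapezoidal area under the percent-change curve between block start and
block end, which is sensitive to both the magnitude and the duration of the
response.

Model predictions have no intrinsic baseline, so a constant offset (default
1 signal unit) is added before the percent-change step; shapes and AUC
comparisons are invariant to this choice up to scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .cogmodel import BlockResult, ExperimentResult, TraceEvent

TR = 2.0
#: baseline scans flanking a block: 7 pre-onset, 8 post-task rest scans
N_PRE_SCANS = 7
N_POST_SCANS = 8


@dataclass(frozen=True)
class HRFParams:
    """Gamma hemodynamic response parameters (per ROI/module).

    ``m`` is the free per-ROI magnitude.  Its default puts the predicted
    response around 1-2% of the unit baseline signal, the scale regime of
    real BOLD; percent-change shapes and AUC orderings only require that
    the response stays small relative to baseline.
    """

    m: float = 2e-4
    s: float = 0.75
    alpha: float = 6.0

    def validate(self) -> None:
        if self.m <= 0 or self.s <= 0 or self.alpha <= 0:
            raise ValueError("HRF parameters must be positive")


@dataclass
class DemandFunction:
    """Binary module-demand samples on a fine grid starting at ``t0``."""

    grid_dt: float
    values: np.ndarray
    t0: float = 0.0

    @property
    def duration(self) -> float:
        return len(self.values) * self.grid_dt


@dataclass
class BOLDSeries:
    """TR-sampled signal; ``kind`` is 'raw' or 'percent_change'."""

    tr: float
    values: np.ndarray
    t0: float = 0.0
    kind: str = "raw"

    def times(self) -> np.ndarray:
        return self.t0 + self.tr * np.arange(len(self.values))


def trace_to_demand(
    trace: list[TraceEvent],
    module: str,
    grid_dt: float = 0.010,
    window: tuple[float, float] = (0.0, 62.0),
) -> DemandFunction:
    """Discretize one module's event intervals to a 0-1 demand function.

    Events are half-open intervals ``[onset, onset+duration)``; their edges
    are rounded to the nearest grid tick.  Overlapping events for the same
    module are rejected.
    """
    t0, t1 = window
    n = int(round((t1 - t0) / grid_dt))
    values = np.zeros(n, dtype=np.uint8)
    events = sorted((e for e in trace if e.module == module),
                    key=lambda e: e.onset)
    last_end = -np.inf
    for e in events:
        if e.onset < last_end - 1e-9:
            raise ValueError(
                f"overlapping {module} events at t={e.onset:.3f}")
        last_end = e.end
        i0 = int(round((e.onset - t0) / grid_dt))
        i1 = int(round((e.end - t0) / grid_dt))
        values[max(i0, 0):max(i1, 0)] = 1
    return DemandFunction(grid_dt=grid_dt, values=values, t0=t0)


def hrf(t, params: HRFParams = HRFParams()):
    """Gamma HRF ``m * (t/s)**alpha * exp(-t/s)``; zero for ``t < 0``."""
    params.validate()
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / params.s
    out[pos] = params.m * x ** params.alpha * np.exp(-x)
    return out if out.ndim else float(out)


def hrf_kernel(params: HRFParams, grid_dt: float,
               duration: float = 32.0) -> np.ndarray:
    """Discrete HRF kernel on the fine grid.

    Each tap is the HRF at the midpoint of its grid bin (midpoint rule), so
    the convolution's quadrature error is O(grid_dt**2) and halving the grid
    leaves TR samples essentially unchanged.  32 s captures the gamma tail
    to <1e-6 of its mass for the default shape.
    """
    n = int(round(duration / grid_dt))
    t = (np.arange(n) - 0.5) * grid_dt
    return hrf(t, params)


def predict_bold(
    demand: DemandFunction,
    params: HRFParams = HRFParams(),
    tr: float = TR,
    kernel_duration: float = 32.0,
) -> BOLDSeries:
    """Convolve demand with the HRF on the fine grid, sample at the TR.

    The result is linear in ``m`` and additive over disjoint demand
    segments.  ``tr`` must be a multiple of the demand grid step.
    """
    step = tr / demand.grid_dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError("grid_dt must divide tr")
    step = int(round(step))
    kernel = hrf_kernel(params, demand.grid_dt, duration=kernel_duration)
    fine = fftconvolve(demand.values.astype(float), kernel)[:len(demand.values)]
    fine *= demand.grid_dt
    return BOLDSeries(tr=tr, values=fine[::step].copy(), t0=demand.t0,
                      kind="raw")


def add_baseline(series: BOLDSeries, offset: float = 1.0) -> BOLDSeries:
    """Add a constant baseline signal level to a raw model prediction."""
    return BOLDSeries(tr=series.tr, values=series.values + offset,
                      t0=series.t0, kind=series.kind)


def percent_change(series: BOLDSeries, n_pre: int = N_PRE_SCANS,
                   n_post: int = N_POST_SCANS) -> BOLDSeries:
    """Percent change from the flanking-rest baseline.

    The baseline is the mean of the first ``n_pre`` and the last ``n_post``
    scans of the block-centred series.
    """
    v = series.values
    if len(v) < n_pre + n_post:
        raise ValueError("series too short for the requested baseline scans")
    baseline = float(np.mean(np.concatenate([v[:n_pre], v[-n_post:]])))
    if baseline == 0:
        raise ZeroDivisionError("degenerate baseline (mean of rest scans is 0)")
    return BOLDSeries(tr=series.tr, values=100.0 * (v - baseline) / baseline,
                      t0=series.t0, kind="percent_change")


def auc(series: BOLDSeries, window: tuple[float, float]) -> float:
    """Trapezoidal area under the curve over ``window`` (percent*seconds).

    Window edges are snapped to the nearest scan.
    """
    w0, w1 = window
    i0 = int(round((w0 - series.t0) / series.tr))
    i1 = int(round((w1 - series.t0) / series.tr))
    i0, i1 = max(i0, 0), min(i1, len(series.values) - 1)
    if i1 <= i0:
        raise ValueError("empty AUC window")
    return float(np.trapezoid(series.values[i0:i1 + 1], dx=series.tr))


# ---------------------------------------------------------------------------
# block-level pipeline
# ---------------------------------------------------------------------------

def block_bold(
    block: BlockResult,
    module: str,
    params: HRFParams = HRFParams(),
    grid_dt: float = 0.010,
    tr: float = TR,
    pre_rest: float = N_PRE_SCANS * TR,
    post_rest: float = N_POST_SCANS * TR,
    baseline_offset: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[BOLDSeries, BOLDSeries]:
    """Predict one block's (raw, percent-change) series for one module.

    The series spans the 7 pre-onset rest scans, the cue+task window and the
    8 post-task rest scans.  Optional white Gaussian scan noise (signal
    units) is added to the raw series before the percent-change step.
    """
    d = block.design
    task_end = d.cue_duration + d.task_duration
    window = (-pre_rest, task_end + post_rest)
    demand = trace_to_demand(block.trace, module, grid_dt=grid_dt,
                             window=window)
    raw = add_baseline(predict_bold(demand, params, tr=tr), baseline_offset)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("scan noise requires an rng")
        raw = BOLDSeries(tr=raw.tr,
                         values=raw.values + rng.normal(0, noise_sd,
                                                        len(raw.values)),
                         t0=raw.t0, kind=raw.kind)
    return raw, percent_change(raw)


def block_auc(block: BlockResult, module: str,
              params: HRFParams = HRFParams(), **kwargs) -> float:
    """AUC of the percent-change prediction between block start and end."""
    _, pct = block_bold(block, module, params, **kwargs)
    d = block.design
    return auc(pct, (d.cue_duration, d.cue_duration + d.task_duration))


def condition_auc(
    experiments: ExperimentResult | list[ExperimentResult],
    module: str,
    params: HRFParams = HRFParams(),
    **kwargs,
) -> dict[str, float]:
    """Mean per-block AUC by condition over one or more experiments."""
    if isinstance(experiments, ExperimentResult):
        experiments = [experiments]
    sums: dict[str, list[float]] = {}
    for exp in experiments:
        for block in exp.blocks:
            sums.setdefault(block.condition, []).append(
                block_auc(block, module, params, **kwargs))
    return {c: float(np.mean(v)) for c, v in sums.items()}
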