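"""Minimal ACT-R-style discrete-event simulator for the three task strategies.

The engine replays, trial by trial, the serial stream of module actions an
ACT-R model performs: a production (procedural step, 50 ms) precedes every
module action; visual encoding takes 85 ms per object; updating the problem
state (the intermediate task representation held in parietal cortex) takes a
fitted 400 ms; a declarative retrieval of a fact with activation ``A`` takes
``F * exp(-A)`` seconds with latency factor ``F`` (fitted to 0.4); a button
press takes 260 ms.  Each action is emitted as a :class:`TraceEvent` so that
module demand can later be convolved into a BOLD prediction.

Strategies (one per condition):

* **Rea** - encode the first two numbers, retrieve their direction (+/-) and
  the relation (difference), each represented in the problem state; encode
  the third number and retrieve the second direction.  If the directions
  differ the series is answered invalid immediately (no second relation
  retrieval); otherwise the second relation is retrieved and compared before
  answering.
* **Cal** - encode the equation, retrieve the intermediate result by rote
  memory, represent it, retrieve the final result, represent it, respond.
* **Jud** - encode the numbers one by one, halting as soon as the target
  ``10`` is found; represent the answer and respond.  No declarative
  retrievals are needed.

Mis-retrievals corrupt the answer (not the path): each retrieval fails with
a logistic probability driven by the distance of the fact's activation from
the retrieval threshold, scaled by the activation noise.  With zero
activation noise the engine is fully deterministic and error-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stimuli import (CAL, JUD, JUD_TARGET, REA, BlockDesign, DesignParams,
                      RunDesign, Stimulus, StimulusConfig, build_runs,
                      DEFAULT_STIM_CONFIG, DEFAULT_DESIGN)

MODULES = ("visual", "problem_state", "declarative", "procedural", "motor")

#: fact-class activations (calibrated so that simulated trials/block and RTs
#: reproduce the observed behavioral means; see docs/methods.md)
DEFAULT_ACTIVATIONS = {
    "instruction": 0.0,    # block-start instruction chunk
    "direction": 1.386,    # order of two numbers (fast, ~0.10 s)
    "relation": -0.235,    # difference between two numbers (~0.51 s)
    "rote": 1.386,         # first-step arithmetic fact, rote (~0.10 s)
    "arithmetic": -0.70,   # second-step result, deliberate (~0.81 s)
}


@dataclass
class EngineParams:
    """Timing and activation parameters of the cognitive engine.

    Durations are seconds.  ``latency_factor`` and ``problem_state_dt`` are
    the two fitted parameters (0.4 s each); the remaining timings are the
    architecture's published defaults.
    """

    latency_factor: float = 0.4
    problem_state_dt: float = 0.400
    visual_encode_dt: float = 0.085
    production_dt: float = 0.050
    motor_dt: float = 0.260
    activation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVATIONS))
    activation_noise_sd: float = 0.25
    retrieval_threshold: float = -3.5
    #: multiplies activation_noise_sd into the logistic error scale
    error_noise_gain: float = 4.0
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("latency_factor", "problem_state_dt", "visual_encode_dt",
                     "production_dt", "motor_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.activation_noise_sd < 0:
            raise ValueError("activation_noise_sd must be >= 0")


@dataclass(frozen=True)
class TraceEvent:
    module: str
    onset: float
    duration: float
    label: str

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class TrialResult:
    stimulus: Stimulus
    rt: float
    correct: bool
    timed_out: bool
    trace: list[TraceEvent]
    option_phase_dt: float
    onset: float = 0.0  # seconds from block start, set by run_block


@dataclass
class BlockResult:
    design: BlockDesign
    trials: list[TrialResult]
    n_completed: int
    n_truncated: int
    trace: list[TraceEvent]
    run_index: int = 0

    @property
    def condition(self) -> str:
        return self.design.condition


@dataclass
class ExperimentResult:
    blocks: list[BlockResult]
    params: EngineParams

    def blocks_of(self, condition: str) -> list[BlockResult]:
        return [b for b in self.blocks if b.condition == condition]


def retrieval_time(activation: float, latency_factor: float) -> float:
    """Declarative retrieval latency ``F * exp(-A)``: frequently and recently
    used facts (high activation) come back faster."""
    if latency_factor <= 0:
        raise ValueError("latency factor must be positive")
    return latency_factor * math.exp(-activation)


class _Path:
    """Serial accumulator of module actions for one trial (or block cue)."""

    def __init__(self, params: EngineParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.t = 0.0
        self.events: list[TraceEvent] = []
        self.misretrieved = False

    def _emit(self, module: str, duration: float, label: str) -> None:
        self.events.append(TraceEvent(module, self.t, duration, label))
        self.t += duration

    def prod(self, label: str) -> None:
        self._emit("procedural", self.p.production_dt, label)

    def encode(self, label: str) -> None:
        self.prod("request-" + label)
        self._emit("visual", self.p.visual_encode_dt, label)

    def represent(self, label: str) -> None:
        self.prod("request-" + label)
        self._emit("problem_state", self.p.problem_state_dt, label)

    def press(self, label: str = "press") -> None:
        self.prod("request-" + label)
        self._emit("motor", self.p.motor_dt, label)

    def retrieve(self, fact_class: str, label: str) -> None:
        p = self.p
        a = p.activation[fact_class]
        noise = (self.rng.normal(0.0, p.activation_noise_sd)
                 if p.activation_noise_sd > 0 else 0.0)
        dt = retrieval_time(a + noise, p.latency_factor)
        self.prod("request-" + label)
        self._emit("declarative", dt, label)
        scale = p.error_noise_gain * p.activation_noise_sd
        if scale > 0:
            p_err = 1.0 / (1.0 + math.exp((a - p.retrieval_threshold) / scale))
            if self.rng.random() < p_err:
                self.misretrieved = True


def _option_phase(path: _Path) -> None:
    path.encode("encode-options")
    path.prod("select-option")
    path.press("press-option")


def _finish(path: _Path, stimulus: Stimulus, timeout: float) -> TrialResult:
    """Apply the response timeout and append the option-selection phase."""
    if path.t > timeout:
        trace = [e for e in path.events if e.onset < timeout]
        if trace and trace[-1].end > timeout:
            last = trace[-1]
            trace[-1] = TraceEvent(last.module, last.onset,
                                   timeout - last.onset, last.label)
        return TrialResult(stimulus, rt=timeout, correct=False,
                           timed_out=True, trace=trace, option_phase_dt=0.0)
    rt = path.t
    _option_phase(path)
    return TrialResult(stimulus, rt=rt, correct=not path.misretrieved,
                       timed_out=False, trace=path.events,
                       option_phase_dt=path.t - rt)


def rea_strategy(stimulus: Stimulus, params: EngineParams,
                 rng: np.random.Generator, timeout: float = 10.0) -> TrialResult:
    if stimulus.condition != REA:
        raise ValueError("rea_strategy requires a Rea stimulus")
    a, b, c = stimulus.elements
    path = _Path(params, rng)
    path.encode("encode-n1")
    path.encode("encode-n2")
    path.retrieve("direction", "retrieve-direction-1")
    path.represent("represent-direction")
    path.retrieve("relation", "retrieve-relation-1")
    path.represent("represent-relation")
    path.encode("encode-n3")
    path.retrieve("direction", "retrieve-direction-2")
    path.prod("compare-directions")
    same_direction = (b - a > 0) == (c - b > 0) and b != a and c != b
    if same_direction:
        path.retrieve("relation", "retrieve-relation-2")
        path.prod("compare-relations")
    path.represent("represent-answer")
    path.press()
    return _finish(path, stimulus, timeout)


def cal_strategy(stimulus: Stimulus, params: EngineParams,
                 rng: np.random.Generator, timeout: float = 10.0) -> TrialResult:
    if stimulus.condition != CAL:
        raise ValueError("cal_strategy requires a Cal stimulus")
    path = _Path(params, rng)
    for label in ("encode-n1", "encode-op1", "encode-n2", "encode-op2",
                  "encode-n3"):
        path.encode(label)
    path.retrieve("rote", "retrieve-intermediate")
    path.represent("represent-intermediate")
    path.retrieve("arithmetic", "retrieve-result")
    path.represent("represent-answer")
    path.press()
    return _finish(path, stimulus, timeout)


def jud_strategy(stimulus: Stimulus, params: EngineParams,
                 rng: np.random.Generator, timeout: float = 10.0) -> TrialResult:
    if stimulus.condition != JUD:
        raise ValueError("jud_strategy requires a Jud stimulus")
    path = _Path(params, rng)
    for i, x in enumerate(stimulus.elements):
        path.encode(f"encode-n{i + 1}")
        if x == JUD_TARGET:
            break
    path.prod("decide")
    path.represent("represent-answer")
    path.press()
    return _finish(path, stimulus, timeout)


_STRATEGIES = {REA: rea_strategy, CAL: cal_strategy, JUD: jud_strategy}


def run_trial(stimulus: Stimulus, params: EngineParams,
              rng: np.random.Generator, timeout: float = 10.0) -> TrialResult:
    return _STRATEGIES[stimulus.condition](stimulus, params, rng, timeout)


def _cue_events(condition: str, params: EngineParams,
                rng: np.random.Generator) -> tuple[list[TraceEvent], float]:
    """Block cue: encode the cue, represent it, retrieve the instruction."""
    path = _Path(params, rng)
    path.encode("encode-cue")
    path.represent("represent-cue")
    path.retrieve("instruction", "retrieve-instruction")
    return path.events, path.t


def run_block(block: BlockDesign, params: EngineParams,
              rng: np.random.Generator, run_index: int = 0) -> BlockResult:
    """Execute one self-paced block.

    Trials run back to back (stimulus phase up to the first press, then the
    option-selection phase, then the ISI) inside the task window that opens
    when the cue ends.  A trial whose first press would fall past the window
    close is truncated and not counted.  Timed-out trials count as completed
    errors and skip the option phase.  The merged trace (cue included) is
    clipped to the cue+task window; no activity occurs during rest.
    """
    window_end = block.cue_duration + block.task_duration
    trace, cue_end = _cue_events(block.condition, params, rng)
    t = max(block.cue_duration, cue_end)
    trials: list[TrialResult] = []
    n_truncated = 0
    for stimulus in block.stimulus_pool:
        if t >= window_end:
            break
        trial = run_trial(stimulus, params, rng, timeout=block.timeout)
        if t + trial.rt > window_end:
            n_truncated += 1
            break
        trial.onset = t
        trials.append(trial)
        trace.extend(TraceEvent(e.module, e.onset + t, e.duration, e.label)
                     for e in trial.trace)
        t += trial.rt + trial.option_phase_dt + block.isi
    clipped = []
    for e in trace:
        if e.onset >= window_end:
            continue
        if e.end > window_end:
            e = TraceEvent(e.module, e.onset, window_end - e.onset, e.label)
        clipped.append(e)
    return BlockResult(block, trials, n_completed=len(trials),
                       n_truncated=n_truncated, trace=clipped,
                       run_index=run_index)


def run_design(runs: list[RunDesign], params: EngineParams,
               rng: np.random.Generator) -> ExperimentResult:
    """Simulate a pre-built multi-run design with one engine RNG."""
    params.validate()
    blocks = [run_block(block, params, rng, run_index=run.run_index)
              for run in runs for block in run.blocks]
    return ExperimentResult(blocks, params)


def run_experiment(
    params: EngineParams | None = None,
    n_runs: int = 2,
    seed: int | None = None,
    stim_config: StimulusConfig = DEFAULT_STIM_CONFIG,
    design: DesignParams = DEFAULT_DESIGN,
    runs: list[RunDesign] | None = None,
) -> ExperimentResult:
    """Generate a design (unless given) and simulate it.

    The seed fans out into independent design and engine streams, so the
    whole experiment is reproducible from one integer.
    """
    params = EngineParams() if params is None else params
    ss = np.random.SeedSequence(params.rng_seed if seed is None else seed)
    design_ss, engine_ss = ss.spawn(2)
    if runs is None:
        runs = build_runs(np.random.default_rng(design_ss), n_runs=n_runs,
                          config=stim_config, design=design)
    return run_design(runs, params, np.random.default_rng(engine_ss))


def run_many(
    n_experiments: int = 100,
    params: EngineParams | None = None,
    seed: int = 0,
    n_runs: int = 2,
    stim_config: StimulusConfig = DEFAULT_STIM_CONFIG,
    design: DesignParams = DEFAULT_DESIGN,
) -> list[ExperimentResult]:
    """Run the model repeatedly (the headline analysis uses 100 runs)."""
    children = np.random.SeedSequence(seed).spawn(n_experiments)
    out = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(run_experiment(params, n_runs=n_runs, seed=sub_seed,
                                  stim_config=stim_config, design=design))
    return out
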