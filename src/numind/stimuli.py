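"""Task problems and block/run designs for a self-paced three-condition numeric experiment.

Three problem types are generated:

``Rea``
    Numerical inductive reasoning. A three-number series such as ``5:11:17``
    built from a constant additive rule (here ``+6``); the participant judges
    whether the series follows a single rule (valid) or not (invalid, e.g.
    ``19:14:17`` whose steps are ``-5`` and ``+3``).
``Cal``
    Three-term calculation such as ``13 - 5 + 7``; the participant computes
    the result and later picks it from two nearby answer options.
``Jud``
    Perceptual judgment: decide whether the digit ``10`` occurs in a series
    such as ``10:44:7``.

All numbers lie in 1-50 and only addition/subtraction is used, with the two
operations (and rule signs) counterbalanced within a block.  Blocks are
30 s self-paced task windows preceded by a 2 s cue and followed by 30 s rest;
a run holds 9 blocks, 3 per condition, with no condition appearing three
times in a row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REA = "Rea"
CAL = "Cal"
JUD = "Jud"
CONDITIONS = (REA, CAL, JUD)

#: judgment target digit
JUD_TARGET = 10


class GenerationError(RuntimeError):
    """Raised when constrained stimulus/design sampling fails."""


@dataclass(frozen=True)
class StimulusConfig:
    """Ranges and counterbalancing constants for problem generation."""

    number_range: tuple[int, int] = (1, 50)
    #: |rule| for valid series; kept within single-retrieval arithmetic facts
    rule_magnitudes: tuple[int, int] = (2, 9)
    #: allowed |foil - correct| for Cal answer options
    foil_distances: tuple[int, ...] = (1, 2)
    #: problems pre-generated per block; ample for any self-paced pace
    pool_size: int = 12
    #: the single invalid Rea item lands uniformly in this many leading slots,
    #: so it is presented even in slow blocks
    rea_invalid_prefix: int = 5


@dataclass(frozen=True)
class DesignParams:
    """Block/run timing constants (seconds)."""

    cue_duration: float = 2.0
    task_duration: float = 30.0
    rest_duration: float = 30.0
    isi: float = 2.0
    timeout: float = 10.0
    blocks_per_condition: int = 3


DEFAULT_STIM_CONFIG = StimulusConfig()
DEFAULT_DESIGN = DesignParams()


@dataclass(frozen=True)
class Stimulus:
    """One problem of any condition.

    ``operators`` is set for Cal only, ``rule`` for valid Rea only.
    ``options`` is the (left, right) answer pair shown after the first
    button press; ``correct_side`` says where the correct answer sits.
    """

    condition: str
    elements: tuple[int, int, int]
    operators: tuple[str, str] | None = None
    rule: int | None = None
    correct_answer: int | str = 0
    options: tuple = ()
    correct_side: str = "left"

    def text(self) -> str:
        if self.condition == CAL:
            assert self.operators is not None
            a, b, c = self.elements
            return f"{a}{self.operators[0]}{b}{self.operators[1]}{c}"
        return ":".join(str(e) for e in self.elements)


@dataclass(frozen=True)
class BlockDesign:
    condition: str
    stimulus_pool: tuple[Stimulus, ...]
    cue_duration: float = 2.0
    task_duration: float = 30.0
    rest_duration: float = 30.0
    isi: float = 2.0
    timeout: float = 10.0


@dataclass(frozen=True)
class RunDesign:
    blocks: tuple[BlockDesign, ...]
    run_index: int = 0


# ---------------------------------------------------------------------------
# single problems
# ---------------------------------------------------------------------------

def series_rule(triple) -> int | None:
    """Return the constant difference of a three-number series, or None.

    ``(5, 11, 17) -> 6``; ``(19, 14, 17) -> None``.  A flat series
    (difference 0) does not count as a rule.
    """
    if len(triple) != 3:
        raise ValueError("a series has exactly three elements")
    for x in triple:
        if isinstance(x, bool) or not isinstance(x, (int, np.integer)):
            raise TypeError(f"series elements must be integers, got {x!r}")
    a, b, c = (int(x) for x in triple)
    d = b - a
    if d != 0 and c - b == d:
        return d
    return None


def _sign_value(rule_sign: str) -> int:
    if rule_sign in ("+", "plus"):
        return 1
    if rule_sign in ("-", "−", "minus"):
        return -1
    raise ValueError(f"rule_sign must be '+' or '-', got {rule_sign!r}")


def generate_rea_problem(
    rng: np.random.Generator,
    valid: bool = True,
    rule_sign: str = "+",
    config: StimulusConfig = DEFAULT_STIM_CONFIG,
) -> Stimulus:
    """Generate one series problem.

    Valid problems have both steps equal to a signed rule ``d`` with
    ``sign(d)`` given by *rule_sign*.  Invalid problems use two steps of
    opposite direction (as in ``19:14:17``), so no single rule exists.
    """
    lo, hi = config.number_range
    mlo, mhi = config.rule_magnitudes
    s = _sign_value(rule_sign)
    if valid:
        d = s * int(rng.integers(mlo, mhi + 1))
        a_lo, a_hi = max(lo, lo - 2 * d), min(hi, hi - 2 * d)
        if a_lo > a_hi:
            raise GenerationError(f"no feasible series for rule {d:+d}")
        a = int(rng.integers(a_lo, a_hi + 1))
        elements = (a, a + d, a + 2 * d)
        rule: int | None = d
        answer = "valid"
    else:
        d1 = s * int(rng.integers(mlo, mhi + 1))
        d2 = -s * int(rng.integers(mlo, mhi + 1))
        a_lo = max(lo, lo - d1, lo - d1 - d2)
        a_hi = min(hi, hi - d1, hi - d1 - d2)
        if a_lo > a_hi:
            raise GenerationError("no feasible invalid series")
        a = int(rng.integers(a_lo, a_hi + 1))
        elements = (a, a + d1, a + d1 + d2)
        rule = None
        answer = "invalid"
    side = "left" if rng.random() < 0.5 else "right"
    options = ("valid", "invalid") if side == "left" else ("invalid", "valid")
    if answer == "invalid":
        options = tuple(reversed(options))
    return Stimulus(REA, elements, rule=rule, correct_answer=answer,
                    options=options, correct_side=side)


_OPERATOR_PAIRS = (("+", "-"), ("-", "+"), ("+", "+"), ("-", "-"))


def _apply(a: int, op: str, b: int) -> int:
    return a + b if op == "+" else a - b


def generate_cal_problem(
    rng: np.random.Generator,
    operators: tuple[str, str] | None = None,
    config: StimulusConfig = DEFAULT_STIM_CONFIG,
) -> Stimulus:
    """Generate one three-term equation with both the intermediate and the
    final result inside the number range, plus a foil answer 1-2 away."""
    lo, hi = config.number_range
    if operators is None:
        operators = _OPERATOR_PAIRS[int(rng.integers(len(_OPERATOR_PAIRS)))]
    for _ in range(10_000):
        a, b, c = (int(x) for x in rng.integers(lo, hi + 1, size=3))
        inter = _apply(a, operators[0], b)
        if not lo <= inter <= hi:
            continue
        final = _apply(inter, operators[1], c)
        if not lo <= final <= hi:
            continue
        dist = int(rng.choice(config.foil_distances))
        foil = final + dist * (1 if rng.random() < 0.5 else -1)
        side = "left" if rng.random() < 0.5 else "right"
        options = (final, foil) if side == "left" else (foil, final)
        return Stimulus(CAL, (a, b, c), operators=operators,
                        correct_answer=final, options=options,
                        correct_side=side)
    raise GenerationError("could not sample a feasible equation")


def generate_jud_problem(
    rng: np.random.Generator,
    contains_target: bool,
    target_position: int | None = None,
    config: StimulusConfig = DEFAULT_STIM_CONFIG,
) -> Stimulus:
    """Generate one target-detection series (is ``10`` present?)."""
    lo, hi = config.number_range
    if contains_target and target_position is None:
        target_position = int(rng.integers(3))
    elements = []
    for i in range(3):
        if contains_target and i == target_position:
            elements.append(JUD_TARGET)
            continue
        while True:
            x = int(rng.integers(lo, hi + 1))
            if x != JUD_TARGET:
                elements.append(x)
                break
    answer = "present" if contains_target else "absent"
    side = "left" if rng.random() < 0.5 else "right"
    options = ("present", "absent") if side == "left" else ("absent", "present")
    if answer == "absent":
        options = tuple(reversed(options))
    return Stimulus(JUD, tuple(elements), correct_answer=answer,
                    options=options, correct_side=side)


# ---------------------------------------------------------------------------
# blocks and runs
# ---------------------------------------------------------------------------

def build_block(
    rng: np.random.Generator,
    condition: str,
    config: StimulusConfig = DEFAULT_STIM_CONFIG,
    design: DesignParams = DEFAULT_DESIGN,
) -> BlockDesign:
    """Pre-generate one block's stimulus pool with its counterbalancing.

    Rea: rule signs split 50/50, exactly one invalid item placed uniformly
    within the first ``rea_invalid_prefix`` slots.  Cal: each operator
    appears equally often across the pool.  Jud: the target is present in
    half the items with its position counterbalanced.
    """
    n = config.pool_size
    pool: list[Stimulus] = []
    if condition == REA:
        signs = ["+"] * (n // 2) + ["-"] * (n - n // 2)
        rng.shuffle(signs)
        invalid_at = int(rng.integers(min(config.rea_invalid_prefix, n)))
        for i, sgn in enumerate(signs):
            pool.append(generate_rea_problem(rng, valid=(i != invalid_at),
                                             rule_sign=sgn, config=config))
    elif condition == CAL:
        reps = -(-n // len(_OPERATOR_PAIRS))
        pairs = list(_OPERATOR_PAIRS) * reps
        pairs = pairs[:n]
        rng.shuffle(pairs)
        for ops in pairs:
            pool.append(generate_cal_problem(rng, operators=ops, config=config))
    elif condition == JUD:
        n_present = n // 2
        positions = [i % 3 for i in range(n_present)]
        specs = [(True, p) for p in positions] + [(False, None)] * (n - n_present)
        rng.shuffle(specs)
        for present, pos in specs:
            pool.append(generate_jud_problem(rng, present, pos, config=config))
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return BlockDesign(condition, tuple(pool),
                       cue_duration=design.cue_duration,
                       task_duration=design.task_duration,
                       rest_duration=design.rest_duration,
                       isi=design.isi, timeout=design.timeout)


def _has_triple_run(order: list[str]) -> bool:
    return any(order[i] == order[i + 1] == order[i + 2]
               for i in range(len(order) - 2))


def build_run(
    rng: np.random.Generator,
    run_index: int = 0,
    config: StimulusConfig = DEFAULT_STIM_CONFIG,
    design: DesignParams = DEFAULT_DESIGN,
) -> RunDesign:
    """Build one run: 3 blocks per condition in a randomized order with no
    condition appearing three times consecutively."""
    order = [c for c in CONDITIONS for _ in range(design.blocks_per_condition)]
    for _ in range(1000):
        rng.shuffle(order)
        if not _has_triple_run(order):
            break
    else:  # pragma: no cover - p(fail) < 1e-200
        raise GenerationError("could not sample a valid block order")
    blocks = tuple(build_block(rng, c, config=config, design=design)
                   for c in order)
    return RunDesign(blocks, run_index=run_index)


def build_runs(
    seed_or_rng,
    n_runs: int = 2,
    config: StimulusConfig = DEFAULT_STIM_CONFIG,
    design: DesignParams = DEFAULT_DESIGN,
) -> list[RunDesign]:
    """Build the full experimental design (default 2 runs)."""
    if isinstance(seed_or_rng, np.random.Generator):
        rng = seed_or_rng
    else:
        rng = np.random.default_rng(seed_or_rng)
    return [build_run(rng, run_index=r, config=config, design=design)
            for r in range(n_runs)]
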