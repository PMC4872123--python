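"""Engine behavior: retrieval latencies, strategy traces, block scheduling."""

import math

import numpy as np
import pytest

from numind import (CAL, JUD, REA, EngineParams, cal_strategy,
                    generate_cal_problem, generate_jud_problem,
                    generate_rea_problem, jud_strategy, rea_strategy,
                    retrieval_time, run_block, run_experiment)
from numind.cogmodel import MODULES
from numind.stimuli import build_block


def _retrievals(trial, label_prefix):
    return [e for e in trial.trace if e.module == "declarative"
            and e.label.startswith(label_prefix)]


def test_retrieval_time_values():
    assert retrieval_time(0.0, 0.4) == pytest.approx(0.4)
    assert retrieval_time(-math.log(2), 0.4) == pytest.approx(0.8)
    # monotone decreasing in activation
    times = [retrieval_time(a, 0.4) for a in np.linspace(-2, 2, 9)]
    assert all(t1 > t2 for t1, t2 in zip(times, times[1:]))
    with pytest.raises(ValueError):
        retrieval_time(0.0, 0.0)


class TestStrategyTraces:
    """Strategy structure: which retrievals occur, and hand-computed RTs.

    With every activation at 0 each retrieval takes exactly 0.4 s, so the
    critical path is a sum of known constants: productions 0.05 s, visual
    encodes 0.085 s, problem-state updates 0.4 s, the press 0.26 s.
    """

    def test_rea_valid_trace(self, zero_act_params, rng):
        s = generate_rea_problem(rng, valid=True)
        t = rea_strategy(s, zero_act_params, rng)
        assert len(_retrievals(t, "retrieve-direction")) == 2
        assert len(_retrievals(t, "retrieve-relation")) == 2
        ps = [e for e in t.trace if e.module == "problem_state"]
        assert len(ps) == 3
        # 3 encodes + 12 productions + 3 ps updates + 4 retrievals + press
        assert t.rt == pytest.approx(2.365 + 4 * 0.4)
        assert t.option_phase_dt == pytest.approx(0.495)
        assert t.correct and not t.timed_out

    def test_rea_invalid_skips_second_relation(self, zero_act_params, rng):
        s = generate_rea_problem(rng, valid=False)
        t = rea_strategy(s, zero_act_params, rng)
        assert len(_retrievals(t, "retrieve-relation")) == 1
        assert len(_retrievals(t, "retrieve-direction")) == 2
        assert t.rt == pytest.approx(2.265 + 3 * 0.4)

    def test_cal_trace(self, zero_act_params, rng):
        s = generate_cal_problem(rng)
        t = cal_strategy(s, zero_act_params, rng)
        decl = [e for e in t.trace if e.module == "declarative"]
        assert len(decl) == 2
        assert t.rt == pytest.approx(1.985 + 2 * 0.4)

    @pytest.mark.parametrize("pos, n_encodes, rt",
                             [(0, 1, 0.945), (1, 2, 1.08), (2, 3, 1.215)])
    def test_jud_target_position(self, zero_act_params, rng, pos, n_encodes,
                                 rt):
        s = generate_jud_problem(rng, True, pos)
        t = jud_strategy(s, zero_act_params, rng)
        encodes = [e for e in t.trace if e.module == "visual"
                   and e.label.startswith("encode-n")]
        assert len(encodes) == n_encodes
        assert not [e for e in t.trace if e.module == "declarative"]
        assert t.rt == pytest.approx(rt)

    def test_jud_absent_encodes_all(self, zero_act_params, rng):
        s = generate_jud_problem(rng, False)
        t = jud_strategy(s, zero_act_params, rng)
        encodes = [e for e in t.trace if e.module == "visual"
                   and e.label.startswith("encode-n")]
        assert len(encodes) == 3
        assert t.rt == pytest.approx(1.215)

    def test_rt_is_critical_path_sum(self, zero_act_params, rng):
        """RT equals the end of the serial event chain up to the press."""
        for gen, strat in [(lambda: generate_rea_problem(rng), rea_strategy),
                           (lambda: generate_cal_problem(rng), cal_strategy),
                           (lambda: generate_jud_problem(rng, False),
                            jud_strategy)]:
            t = strat(gen(), zero_act_params, rng)
            press = [e for e in t.trace if e.module == "motor"][0]
            assert t.rt == pytest.approx(press.end)
            # events are serial: each starts where the previous ended
            stim_events = [e for e in t.trace if e.onset < t.rt]
            for e1, e2 in zip(stim_events, stim_events[1:]):
                assert e2.onset == pytest.approx(e1.end)


def test_trial_determinism():
    params = EngineParams()  # default activation noise
    rng1 = np.random.default_rng(99)
    s = generate_rea_problem(np.random.default_rng(1))
    t1 = rea_strategy(s, params, np.random.default_rng(50))
    t2 = rea_strategy(s, params, np.random.default_rng(50))
    assert t1.rt == t2.rt and t1.correct == t2.correct
    assert t1.trace == t2.trace


def test_noise_zero_accuracy_perfect(zero_act_params, rng):
    block = build_block(rng, REA)
    res = run_block(block, zero_act_params, rng)
    assert all(t.correct for t in res.trials)


def test_trace_no_overlap_per_module(default_experiment):
    for block in default_experiment.blocks:
        for module in MODULES:
            events = sorted((e for e in block.trace if e.module == module),
                            key=lambda e: e.onset)
            for e1, e2 in zip(events, events[1:]):
                assert e2.onset >= e1.end - 1e-9


def test_declarative_demand_ordering(zero_act_params, rng):
    """Per-trial declarative time: Rea > Cal > Jud at equal activations."""
    def decl_time(trial):
        return sum(e.duration for e in trial.trace
                   if e.module == "declarative")
    rea = rea_strategy(generate_rea_problem(rng), zero_act_params, rng)
    cal = cal_strategy(generate_cal_problem(rng), zero_act_params, rng)
    jud = jud_strategy(generate_jud_problem(rng, False), zero_act_params, rng)
    assert decl_time(rea) > decl_time(cal) > decl_time(jud)


class TestBlockScheduling:
    def test_block_against_step_through_oracle(self, zero_act_params):
        """Completed-trial count must match an independent event-by-event
        walk through the self-paced window."""
        rt_of = {REA: {"valid": 3.965, "invalid": 3.465},
                 CAL: 2.785}
        for cond in (REA, CAL, JUD):
            rng = np.random.default_rng(7)
            block = build_block(rng, cond)
            res = run_block(block, zero_act_params,
                            np.random.default_rng(8))
            # oracle: walk the pool, accumulating rt + option + isi
            t, n = 2.0, 0
            for s in block.stimulus_pool:
                if cond == REA:
                    rt = rt_of[REA]["valid" if s.rule is not None
                                    else "invalid"]
                elif cond == CAL:
                    rt = rt_of[CAL]
                else:
                    k = (s.elements.index(10) + 1) if 10 in s.elements else 3
                    rt = 0.81 + 0.135 * k
                if t + rt > 32.0:
                    break
                n += 1
                t += rt + 0.495 + 2.0
            assert res.n_completed == n

    def test_block_time_budget(self, small_cohort):
        """Completed cycles fit in the task window (plus one truncation)."""
        for exp in small_cohort:
            for b in exp.blocks:
                used = sum(t.rt + t.option_phase_dt + b.design.isi
                           for t in b.trials)
                assert used <= b.design.task_duration + b.design.isi \
                    + b.design.timeout

    def test_timeout_produces_error_and_continues(self, rng):
        params = EngineParams(activation_noise_sd=0.0)
        params.activation = dict(params.activation)
        params.activation["relation"] = -4.0  # 21.8 s retrieval
        block = build_block(rng, REA)
        res = run_block(block, params, rng)
        timed_out = [t for t in res.trials if t.timed_out]
        assert timed_out, "slow retrievals should hit the 10 s timeout"
        assert all(t.rt == pytest.approx(10.0) for t in timed_out)
        assert all(not t.correct for t in timed_out)
        assert res.n_completed >= 2  # the block moved on to new problems

    def test_trace_clipped_to_task_window(self, default_experiment):
        for b in default_experiment.blocks:
            end = b.design.cue_duration + b.design.task_duration
            assert all(e.end <= end + 1e-9 for e in b.trace)


class TestExperiment:
    def test_structure_and_determinism(self):
        e1 = run_experiment(seed=3)
        e2 = run_experiment(seed=3)
        assert len(e1.blocks) == 18
        for cond in (REA, CAL, JUD):
            assert len(e1.blocks_of(cond)) == 6
        assert [b.n_completed for b in e1.blocks] == \
            [b.n_completed for b in e2.blocks]
        assert [t.rt for b in e1.blocks for t in b.trials] == \
            [t.rt for b in e2.blocks for t in b.trials]

    def test_condition_orderings(self, small_cohort):
        from numind import summarize_behavior
        s = summarize_behavior(small_cohort)
        assert s.loc[REA, "mean_rt"] > s.loc[CAL, "mean_rt"] \
            > s.loc[JUD, "mean_rt"]
        assert s.loc[JUD, "accuracy"] > s.loc[CAL, "accuracy"] \
            > s.loc[REA, "accuracy"]
        assert s.loc[JUD, "trials_mean"] > s.loc[CAL, "trials_mean"] \
            > s.loc[REA, "trials_mean"]

    def test_jud_blocks_complete_more_trials(self, small_cohort):
        for exp in small_cohort:
            jud = np.mean([b.n_completed for b in exp.blocks_of(JUD)])
            rea = np.mean([b.n_completed for b in exp.blocks_of(REA)])
            assert jud > rea
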