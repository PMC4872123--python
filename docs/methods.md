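# Methods

## The cognitive engine

The engine is a deliberately minimal ACT-R-style simulator: instead of a
production-rule interpreter it replays, per trial, the serial chain of
module actions that the task strategies prescribe.  Every module action is
preceded by one production (procedural) step.  The timing constants are the
architecture's published defaults except where noted:

| parameter            | default | units | meaning |
|----------------------|---------|-------|---------|
| `latency_factor` (F) | 0.4     | s     | declarative retrieval scale; retrieval takes `F·exp(−A)` — *fitted* |
| `problem_state_dt`   | 0.400   | s     | one problem-state (imaginal) update — *fitted* |
| `visual_encode_dt`   | 0.085   | s     | shift attention + encode one object |
| `production_dt`      | 0.050   | s     | one production firing |
| `motor_dt`           | 0.260   | s     | one button press |
| `activation_noise_sd`| 0.25    | —     | Gaussian noise on activation per retrieval |
| `retrieval_threshold`| −3.5    | —     | centre of the mis-retrieval logistic |
| `error_noise_gain`   | 4.0     | —     | scales noise sd into the logistic error scale |

Strategies (condition → module chain):

* **Rea** (valid): encode n1, n2 → retrieve direction → represent →
  retrieve relation → represent → encode n3 → retrieve direction →
  compare → retrieve relation → compare → represent answer → press.
  Four retrievals, three problem-state updates.
* **Rea** (invalid): the second direction differs from the first, so the
  model answers "invalid" immediately — one relation retrieval only.
* **Cal**: encode the five equation tokens → retrieve the intermediate
  result (rote, fast) → represent → retrieve the final result
  (deliberate, slow) → represent → press.  Exactly two retrievals.
* **Jud**: encode numbers sequentially, halting at the target 10 →
  represent answer → press.  No retrievals.

Each block opens with a 2-s cue period in which the model encodes the cue,
represents it, and retrieves the block instruction; trials then run back to
back (stimulus phase → option-selection phase → 2-s ISI) until the 30-s
task window closes.  A trial counts as completed when its first button
press — the recorded RT — falls inside the window; a trial cut off earlier
is truncated and discarded, and a trial exceeding the 10-s response
deadline counts as a completed error.  The option-selection phase (encode
options → select → press, ≈0.5 s) is logged separately from RT.

### Activations and calibration

Fact-class activations are the model's free parameters; the two timing
parameters above were fitted to behavior in the original analysis, and the
activations here are calibrated once against the observed per-condition
behavioral means (4.96 / 5.50 / 8.48 trials per 30-s block):

| fact class   | A      | retrieval time | role |
|--------------|--------|----------------|------|
| instruction  | 0.0    | 0.40 s | block-start instruction chunk |
| direction    | 1.386  | 0.10 s | order of two numbers |
| relation     | −0.235 | 0.51 s | difference between two numbers |
| rote         | 1.386  | 0.10 s | first-step arithmetic fact |
| arithmetic   | −0.70  | 0.81 s | second-step result (deliberate) |

At these defaults the simulated means are 5.00 / 5.54 / 8.00.  The Jud
strategy involves no retrievals, so its trial count is fixed by the
structural constants alone; 8.00 is as close as the architecture's default
timings come to the observed 8.48.

### Error model

The study reports accuracies but no error mechanism.  We use per-retrieval
mis-retrieval: with probability `1/(1 + exp((A − τ)/(g·σ)))` (τ the
retrieval threshold, σ the activation noise sd, g the gain) the retrieved
fact is wrong and the trial's answer is corrupted; the path and its timing
are unchanged.  This is a simplification — a wrong direction retrieval
would really reroute the Rea strategy — chosen so that accuracy and RT can
be calibrated independently.  With σ = 0 the engine is deterministic and
error-free.  Because errors accumulate per retrieval, the accuracy
ordering Jud > Cal > Rea follows structurally from the retrieval counts
(0, 2, 4).

## BOLD prediction

Module demand is binarized on a 10-ms grid (half-open event intervals,
edges rounded to the grid) and convolved with the gamma HRF
`H(t) = m·(t/s)^α·e^(−t/s)`; the fine-grid result is sampled at the 2-s TR.
The discrete kernel uses midpoint taps of `H` over each grid bin, making
the quadrature error O(grid_dt²) so TR samples are stable under grid
refinement.  The kernel spans 32 s, capturing the default gamma's mass to
<1e−6.

Defaults: shape α = 6, scale s = 0.75 s (peak at α·s = 4.5 s).  The
magnitude m is the free per-ROI parameter; its default (2e−4) places the
predicted response at ~1–2% of the unit baseline offset that is added
before the percent-change step.  This response ≪ baseline regime matters:
the baseline is estimated from the 7 pre-onset and 8 post-task rest scans,
and the post-task scans carry hemodynamic spillover, so if the response
were comparable to the baseline the normalization would wash out condition
differences.  AUC is the trapezoidal integral of the percent-change curve
between block start and block end (window edges snapped to the nearest
scan).

Traces are convolved per block (the block-design analysis unit); each
block's series spans 7 pre-rest scans, the 32-s cue+task window and 8
post-rest scans (31 scans).

## Statistics

The repeated-measures ANOVA is the textbook one-way within-subject
partition (condition and subject sums of squares removed from the total),
df = (k−1, (k−1)(n−1)) — (2, 28) for 15 subjects and 3 conditions — with
no sphericity correction.  A degenerate all-equal table returns F = 0.
The Rea-vs-Cal AUC comparison is the two-condition special case,
F(1, n−1), reporting the direction of the difference.

`fit_parameters` grid-searches the latency factor and problem-state
duration against per-condition mean RT and trials/block, each z-scaled by
its spread across the target conditions so seconds and counts weigh
equally (the original fit's objective is unreported; this choice is
configurable by rescaling the targets).  Common random numbers are used
across grid points and ties break toward the smaller latency factor, then
the smaller duration, making the fit deterministic given a seed.

## Synthetic participants

`simulate_participants` emulates a 15-subject cohort: one shared stimulus
design (as in the real study), per-subject engine noise streams, a
per-subject lognormal RT factor (σ = 0.10), per-trial response flips
(p = 0.02) and white Gaussian scan noise (sd = 0.05 signal units) added to
the raw BOLD before percent change.  It does **not** model: autocorrelated
physiological noise, motion, drift, voxel-level spatial structure,
between-subject strategy or parameter variation, or learning across
blocks.  Passing tests on these cohorts therefore demonstrate the
correctness and statistical calibration of the pipeline, not robustness to
realistic fMRI artifacts.

## Numerical and design choices

* The self-paced window bookkeeping treats a trial's cycle as
  RT + option phase + ISI; see above for the completion rule.
* Invalid Rea series use opposite-direction steps (as in the study's
  example `19:14:17`), exercising the early-exit path; the single invalid
  item per block lands uniformly within the first five pool slots so it is
  always presented.  Cal foils sit at |Δ| ∈ {1, 2} from the correct
  answer; valid rules use |d| ∈ [2, 9].  All configurable.
* Demand discretization conserves event duration exactly for grid-aligned
  events and to one grid step per event edge otherwise.
* One master seed fans out through named `SeedSequence` children (design,
  engine, synth, fit); all file writers format floats with `repr`, so
  pipeline outputs are byte-reproducible.
* Problem sizes used by the default test run: 100 model runs for the
  behavioral reproduction, 10,000 problems per condition and 1,000 run
  designs for stimulus invariants, 20 replicates for noisy parameter
  recovery, 500 null replicates for the type-I calibration.

## Known limitations

* The engine hard-codes the three strategies; it is not a general ACT-R
  interpreter, and goal-module bookkeeping is folded into the procedural
  trace.
* RT jitter in synthetic cohorts rescales reported RTs but not the
  underlying traces, so behavioral and BOLD noise are independent by
  construction.
* The Jud trial count (8.00) undershoots the observed 8.48 by ~6%; no free
  parameter governs it (see calibration above).
* Voxelwise GLM results (cluster coordinates, T-scores) require the
  original imaging data and are out of scope; the package analyzes ROI
  timecourses only.
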