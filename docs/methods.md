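# Methods

This note documents the models implemented in `arcpractice`, the defaults
chosen where the published task description leaves choices open, and what
the synthetic learner does and does not capture.

## Task geometry and the In-Channel Fraction

The channel centerline is fixed as the **upper semicircle** (polar angle in
[0, π]) of radius D/2, centered at the midpoint between the start and end
circles, in a continuous-pixel, y-up coordinate frame with the origin at
the arc center. The angular extent of the arc and the start/end circle
radii are not part of the published task constants, so: membership is
purely the annular band test |‖p‖ − D/2| ≤ w/2 within the upper half-plane,
boundaries inclusive (a deterministic, testable tie-break), and the
start/end circles are not modeled as separate regions. A `flip_y` converter
handles y-down screen dumps.

ICF is a **per-recorded-sample fraction** — the literal "proportion of
movements in the channel" — not an arc-length-weighted quantity. It is
therefore only as robust to nonuniform sampling as the definition itself;
the simulator samples uniformly at 120 Hz, so the distinction does not
matter for synthetic data.

## Jerk cost

Both coordinates are filtered with `scipy.signal.savgol_filter`
(polynomial degree 3, derivative order 3, `delta` = 1/sample rate), and the
squared estimates are summed over both dimensions. Three choices are ours:

* **Window length** — 21 samples (~175 ms at 120 Hz), a standard smoothing
  scale for ~1 s wrist movements; configurable via `JerkConfig` and
  recorded in every session-log sidecar.
* **Edge handling** — the first and last half-window of estimates are
  excluded from the sum: SG edge values are polynomial-extrapolation
  artifacts and would otherwise dominate.
* **Units** — derivatives are returned in px/s³ (the sum is px²/s⁶ over
  samples). Published jerk magnitudes are unitless and depend on unstated
  filter settings, so absolute jerk values are not comparable across
  implementations — only within a fixed configuration.

"Third order … of degree 3" is interpreted as derivative order 3 with a
degree-3 polynomial: the sum of squares of the *filtered data* is only a
smoothness cost if the filtered data is the jerk estimate itself, per the
minimum-jerk account of skilled movement.

## Schedulers

**Curriculum learning.** Softmax selection `P_i ∝ exp(w_i^γ)` with γ = 2
applied to the weight *before* exponentiation, exactly as printed. The
reward is the **absolute** difference between the mean ICF of the last d=4
trials and the previous d=4 trials of the same task: the defining text
says "absolute difference" (twice), although the displayed formula prints
a signed one; we follow the text, which also keeps weights nonnegative so
w^γ is well defined for any γ. While a task has fewer than 2d recorded
trials its reward is 0, so its weight decays (β = 0.5) until data accrues;
the calibration sweep guarantees every task one block of history before
training. Only the scheduled task's weight is updated after its block.

A consequence worth noting: with rewards on the ICF scale (≤ ~0.3 in
practice) and γ = 2, the exponent spread `max w² − min w²` is at most a few
hundredths, so the softmax stays close to uniform. The bandit biases
*gently* toward progressing tasks rather than concentrating hard on them.

**Error adaptation.** `N_i = clamp(N·E_i, 0.0715·N, 0.363·N)`. The clamps
guarantee a floor and ceiling but not ΣN_i = N, and no redistribution
mechanism is published, so ours is: excess (when the clamped sum falls
short of N) is added proportionally to the not-yet-capped tasks' errors
(uniformly if those errors are all zero); deficit is removed proportionally
to each free task's headroom above the floor. Both directions freeze tasks
at their bound and converge in ≤ K passes, preserve the error ordering of
the allocation, and are followed by largest-remainder rounding — at block
(4-trial) granularity when building the actual schedule. Per-task errors
are `1 − mean block ICF` from the **calibration** phase, normalized to sum
to 1 (the pre-test uses an 18 px channel that is not in the training set; a
switch allows pre-test-based errors instead). Blocks are interleaved
greedily — always the task with the most remaining blocks among those
differing from the previous block, seeded-random tie-breaks — which
minimizes the longest same-task run.

**Random.** Exactly 12 blocks per width, seeded uniform shuffle.

All three schedulers consume explicitly passed seeded generators; equal
seeds give bit-identical schedules, and there is no hidden global state.

## The synthetic learner

Per width, skill follows an exponential learning curve
`skill(n) = asymptote − (asymptote − initial)·exp(−n/τ)` in *effective*
practice trials n. Three mechanisms make n "effective":

* **Width-graded difficulty** — initial skill rises logistically with
  width (wider = easier), from ≈0.29 at 18 px to ≈0.74 at 55 px, with the
  asymptote 0.45 above it (capped at 0.97).
* **Neighbor transfer** — each trial credits `transfer_coupling` (default
  0.3) effective trials to the widths adjacent in sorted order; nothing is
  published about cross-task transfer, so this is a documented free choice.
* **Functional difficulty** — one trial's credit is `4·s·(1−s)` at current
  skill s: learning per trial peaks at intermediate challenge and falls off
  when a task is far too hard or already mastered (the challenge-point
  account of nominal vs functional difficulty). `challenge_gain=0` disables
  this and restores flat one-credit-per-trial accrual.

Skill maps to motion through a radial-noise function: trajectories sweep
the centerline with a minimum-jerk angular profile θ(t) = π·(10s³−15s⁴+6s⁵)
over MT plus Gaussian timing jitter (s.d. 0.03 s), and the radius carries
Gaussian noise, temporally smoothed over 9 samples (so the jerk cost
responds to noise amplitude rather than white-noise aliasing), with s.d.
falling linearly from 22 px at zero skill to 2 px at mastery. Every trial's
ICF, jerk and relative movement time are measured from the generated
trajectory by the same geometry and smoothness code used for real data.

**Calibration of the defaults.** τ defaults to 80 effective trials, so the
~48 trials per width one session provides leave a learner mid-curve: with
the default noise map this yields a pre-test ICF ≈ 0.41 rising to ≈ 0.54 at
post-test — the modest single-session gain characteristic of this kind of
steering task — rather than implausible full mastery. Heterogeneous cohorts
(`make_cohort`) vary τ (lognormal, σ = 0.45), per-width initial skill
(± 0.08), and the noise ceiling (± 3 px) across learners.

**What the simulator does not capture.** Scores are conditionally Gaussian
around the skill curve — no fatigue, warm-up, motivation, memory
consolidation between days, or forgetting; retention is tested 24 h later
in the protocol but the simulated learner neither consolidates nor forgets
overnight. Trajectories deviate only radially (no angular overshoot, no
submovement corrections). Passing tests therefore demonstrate that the
schedulers and metrics behave correctly and that qualitative schedule-level
contrasts can emerge — not that human effect sizes are reproduced.

On cohort-level contrasts specifically: with a matched heterogeneous cohort
of 24 simulated learners per condition, curriculum learning shows lower
mean final-training jerk than random, lower across-learner jerk s.d. than
random, and fewer task switches than random. It does **not** show lower
across-learner jerk s.d. than error adaptation: under this learner model
the EA allocator — which targets each learner's measured weak widths
directly and interleaves near-perfectly — is at least as strong a
per-learner homogenizer as the weakly-differentiating softmax bandit. The
corresponding human finding evidently rests on mechanisms (engagement,
difficulty-dependent consolidation) this skill model does not encode; the
acceptance test for that contrast is left failing rather than weakened.

## Protocol and numerics

The built-in protocol encodes the published two-day design exactly:
familiarization (1 block, 75 px), pre-test (3 × 4 trials, 18 px),
calibration (7 blocks, each width once, seeded order), training (84 × 4,
widths 25–55 px, D = 800 px, MT = 1 s), post-test (3 × 4), retention
(2 × 12), and five 12-trial transfer blocks with (D, MT) =
(600, 1), (400, 1), (800, 0.7), (600, 0.7), (400, 0.7) at width 18 px.

Numerical conventions: error vectors must sum to 1 within 1e-6; sampling
uniformity for the SG filter is enforced to 0.1% of the sample period;
log-linear learning rates drop zero-ICF blocks with a logged count (jerk is
strictly positive by construction) and return **signed** slopes — reports
that want "higher learning rate" magnitudes must take absolute values
explicitly. Trial counts are rounded by largest remainder with stable
(first-index) tie-breaks. An optional importer for archived human sessions
is deliberately limited to the documented CSV schema
(`read_session_log`); no download logic ships with the package, and all
tests run on synthetic data.
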