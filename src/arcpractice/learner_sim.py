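"""Synthetic learner and trajectory generator.

Stands in for a human participant so the schedulers and movement metrics can
be exercised end-to-end.  The learner has, per channel width, an exponential
learning curve on the ICF scale,

    skill(n) = asymptote - (asymptote - initial) * exp(-n / tau),

indexed by the number of *effective* practice trials n (practice on a width
also credits a configurable fraction to its neighboring widths).  Skill maps
to motor output through a decreasing radial-noise function: a skilled
learner's cursor hugs the channel centerline (high ICF, low jerk), an
unskilled learner's wanders (low ICF, high jerk).  Trajectories follow a
minimum-jerk angular profile along the arc with temporally smoothed Gaussian
radial noise, sampled at 120 Hz over the prescribed movement time plus
Gaussian timing jitter.

Wider channels are easier: initial skill rises logistically with width, so
the simulated cohort reproduces the width-as-nominal-difficulty structure of
the task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_geometry import ArcChannelTask, Trajectory, compute_icf, relative_movement_time
from .smoothness import JerkConfig, jerk_cost
from .schedulers import (
    CurriculumConfig,
    CurriculumScheduler,
    EAConfig,
    ea_allocate_trials,
    ea_build_schedule,
    random_schedule,
)
from .protocol_io import ExperimentProtocol, SessionLog, default_protocol

__all__ = [
    "TaskSkill",
    "LearnerModel",
    "default_learner",
    "make_cohort",
    "skill",
    "icf_response",
    "minimum_jerk_profile",
    "generate_trajectory",
    "simulate_experiment",
    "run_cohort",
    "CONDITIONS",
]

CONDITIONS = ("curriculum", "error_adaptation", "random")


@dataclass(frozen=True)
class TaskSkill:
    """Learning-curve parameters for one channel width."""

    initial_skill: float
    asymptote: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_skill <= self.asymptote <= 1.0:
            raise ValueError(
                f"need 0 <= initial <= asymptote <= 1, got "
                f"{self.initial_skill}, {self.asymptote}"
            )
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class LearnerModel:
    """A synthetic learner: per-width learning curves plus a noise model.

    radial_noise_px maps skill in [0, 1] linearly from ``radial_noise_ceil_px``
    (no skill) down to ``radial_noise_floor_px`` (mastery); the noise is
    temporally smoothed over ``noise_smooth_window`` samples so the jerk cost
    responds to its amplitude rather than to white-noise aliasing.
    transfer_coupling is the fraction of practice credit shared with each
    width adjacent (in sorted order) to the practiced one.

    ``challenge_gain`` implements functional difficulty: the effective
    practice credit of one trial is ``(4 s (1 - s)) ** challenge_gain`` where
    s is the learner's current skill on the practiced width — learning per
    trial peaks at intermediate challenge and falls off when a task is far
    too hard or already mastered.  Set it to 0 for flat (one credit per
    trial) accrual.
    """

    task_params: dict
    score_noise_sd: float = 0.04
    radial_noise_floor_px: float = 2.0
    radial_noise_ceil_px: float = 22.0
    noise_smooth_window: int = 9
    timing_jitter_sd: float = 0.03
    transfer_coupling: float = 0.3
    challenge_gain: float = 1.0
    sample_rate: float = 120.0

    def __post_init__(self) -> None:
        if not self.task_params:
            raise ValueError("learner needs at least one task")
        if self.score_noise_sd < 0 or self.timing_jitter_sd < 0:
            raise ValueError("noise s.d.s must be >= 0")
        if not 0.0 <= self.transfer_coupling <= 1.0:
            raise ValueError("transfer_coupling must be in [0, 1]")
        if self.challenge_gain < 0:
            raise ValueError("challenge_gain must be >= 0")
        if self.radial_noise_floor_px < 0 or self.radial_noise_ceil_px < self.radial_noise_floor_px:
            raise ValueError("need 0 <= noise floor <= noise ceiling")

    def radial_noise_px(self, current_skill: float) -> float:
        """Radial noise s.d. (px) as a decreasing function of skill."""
        s = min(max(float(current_skill), 0.0), 1.0)
        return self.radial_noise_ceil_px - (
            self.radial_noise_ceil_px - self.radial_noise_floor_px
        ) * s

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(sorted(self.task_params))


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def default_learner(
    widths: tuple[float, ...] | None = None,
    *,
    skill_jitter: dict | None = None,
    tau: float = 80.0,
    **overrides,
) -> LearnerModel:
    """A learner with width-graded difficulty over the given channel widths.

    Initial skill rises logistically with width (wider = easier); the
    asymptote sits 0.45 above the initial skill, capped at 0.97.  The default
    time constant of 80 effective trials leaves a learner mid-curve after the
    ~48 trials per width a single session provides, giving the modest
    single-session gains typical of this kind of steering task rather than
    full mastery.  ``skill_jitter`` optionally shifts each width's initial
    skill (used to make heterogeneous cohorts).
    """
    if widths is None:
        widths = tuple(sorted(default_protocol().all_widths))
    params = {}
    for w in widths:
        init = 0.15 + 0.7 * _logistic((w - 35.0) / 12.0)
        if skill_jitter:
            init += skill_jitter.get(w, 0.0)
        init = min(max(init, 0.02), 0.92)
        params[float(w)] = TaskSkill(
            initial_skill=init,
            asymptote=min(init + 0.45, 0.97),
            tau=tau,
        )
    return LearnerModel(task_params=params, **overrides)


def make_cohort(
    n: int,
    seed: int,
    widths: tuple[float, ...] | None = None,
    *,
    tau_sigma: float = 0.45,
    skill_sigma: float = 0.08,
    noise_ceil_sigma: float = 3.0,
) -> list[LearnerModel]:
    """A heterogeneous cohort of n learners.

    Learning speed (tau), per-width starting skill, and motor noise ceiling
    vary across learners, emulating individual differences in how hard each
    width is and how fast it is acquired.
    """
    rng = np.random.default_rng(seed)
    if widths is None:
        widths = tuple(sorted(default_protocol().all_widths))
    cohort = []
    for _ in range(n):
        tau = float(np.exp(rng.normal(np.log(80.0), tau_sigma)))
        jitter = {w: float(rng.normal(0.0, skill_sigma)) for w in widths}
        ceil = float(np.clip(rng.normal(22.0, noise_ceil_sigma), 12.0, 32.0))
        cohort.append(
            default_learner(
                widths, skill_jitter=jitter, tau=tau, radial_noise_ceil_px=ceil
            )
        )
    return cohort


def skill(learner: LearnerModel, width: float, n: float) -> float:
    """Expected ICF-scale skill on a width after n effective practice trials."""
    if n < 0:
        raise ValueError("practice count must be >= 0")
    p = learner.task_params[float(width)]
    return p.asymptote - (p.asymptote - p.initial_skill) * math.exp(-n / p.tau)


def icf_response(
    learner: LearnerModel, width: float, n: float, rng: np.random.Generator
) -> float:
    """A noisy trial-level ICF score: skill plus Gaussian noise, clipped to [0, 1]."""
    s = skill(learner, width, n) + rng.normal(0.0, learner.score_noise_sd)
    return float(np.clip(s, 0.0, 1.0))


def minimum_jerk_profile(s):
    """Minimum-jerk position profile 10 s^3 - 15 s^4 + 6 s^5 on [0, 1].

    Rest-to-rest: value 0 at s=0 and 1 at s=1, with zero velocity and
    acceleration at both endpoints.
    """
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("normalized time must lie in [0, 1]")
    out = arr**3 * (10.0 - 15.0 * arr + 6.0 * arr**2)
    return float(out) if np.isscalar(s) else out


def _smoothed_noise(n: int, sd: float, window: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    if window > 1:
        kernel = np.ones(window) / window
        smooth = np.convolve(white, kernel, mode="same")
        smooth *= math.sqrt(window)  # restore unit interior variance
    else:
        smooth = white
    return sd * smooth


def generate_trajectory(
    learner: LearnerModel,
    task: ArcChannelTask,
    current_skill: float,
    rng: np.random.Generator,
    *,
    min_samples: int = 25,
) -> Trajectory:
    """One simulated trial on ``task`` at the given skill level.

    The cursor sweeps the semicircular centerline with a minimum-jerk angular
    profile over MT (plus timing jitter), at the learner's sample rate; the
    radius carries smoothed Gaussian noise whose s.d. decreases with skill.
    """
    fs = learner.sample_rate
    duration = task.movement_time
    if learner.timing_jitter_sd > 0:
        duration = duration + float(rng.normal(0.0, learner.timing_jitter_sd))
    n = int(round(duration * fs)) + 1
    if n < min_samples:
        raise ValueError(
            f"movement time {task.movement_time}s too short: {n} samples at "
            f"{fs} Hz, need >= {min_samples}"
        )
    timestamps = np.arange(n) / fs
    s = timestamps / timestamps[-1]
    theta = math.pi * minimum_jerk_profile(s)
    radius = task.radius + _smoothed_noise(
        n, learner.radial_noise_px(current_skill), learner.noise_smooth_window, rng
    )
    points = np.column_stack((radius * np.cos(theta), radius * np.sin(theta)))
    return Trajectory(timestamps=timestamps, points=points)


class _PracticeCounter:
    """Per-width effective practice: challenge-weighted, with neighbor credit."""

    def __init__(self, widths: tuple[float, ...], coupling: float, challenge_gain: float) -> None:
        self.counts = {float(w): 0.0 for w in widths}
        order = sorted(self.counts)
        self.neighbors = {
            w: [v for v in (order[i - 1] if i > 0 else None,
                            order[i + 1] if i < len(order) - 1 else None)
                if v is not None]
            for i, w in enumerate(order)
        }
        self.coupling = coupling
        self.challenge_gain = challenge_gain

    def credit(self, width: float, current_skill: float) -> None:
        s = min(max(current_skill, 0.0), 1.0)
        gain = (4.0 * s * (1.0 - s)) ** self.challenge_gain
        self.counts[float(width)] += gain
        for nb in self.neighbors[float(width)]:
            self.counts[nb] += self.coupling * gain


def _normalized_errors(cal_icf: dict, widths: tuple[float, ...]) -> np.ndarray:
    errors = np.array([1.0 - float(np.mean(cal_icf[w])) for w in widths])
    errors = np.clip(errors, 0.0, None)
    total = errors.sum()
    if total <= 0:  # perfect calibration everywhere: fall back to uniform
        return np.full(len(widths), 1.0 / len(widths))
    return errors / total


def simulate_experiment(
    condition: str,
    learner: LearnerModel,
    protocol: ExperimentProtocol | None = None,
    seed: int = 0,
    *,
    jerk_cfg: JerkConfig | None = None,
    cl_cfg: CurriculumConfig | None = None,
    ea_cfg: EAConfig | None = None,
    error_source: str = "calibration",
    participant_id: str = "p0",
) -> SessionLog:
    """Run the full protocol for one learner under one scheduling condition.

    Every trial generates a trajectory, from which ICF, jerk cost, and
    relative movement time are measured; training-phase ICFs feed back into
    the scheduler (online for curriculum learning, one-shot for error
    adaptation).  ``error_source`` selects whether EA errors come from the
    calibration sweep (default) or the pre-test.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if error_source not in ("calibration", "pre_test"):
        raise ValueError("error_source must be 'calibration' or 'pre_test'")
    if protocol is None:
        protocol = default_protocol()
    if jerk_cfg is None:
        jerk_cfg = JerkConfig(sample_rate=learner.sample_rate)
    if cl_cfg is None:
        cl_cfg = CurriculumConfig()

    missing = [w for w in protocol.all_widths if float(w) not in learner.task_params]
    if missing:
        raise ValueError(f"learner has no skill parameters for widths {missing}")

    rng = np.random.default_rng(seed)
    counter = _PracticeCounter(
        tuple(learner.task_params), learner.transfer_coupling, learner.challenge_gain
    )
    cl_sched: CurriculumScheduler | None = None
    if condition == "curriculum":
        cl_sched = CurriculumScheduler(
            list(protocol.training_widths), cl_cfg, np.random.default_rng(rng.integers(2**31))
        )
    phase_scores: dict[str, dict] = {}
    rows = []
    block_counter = 0

    for phase in protocol.phases:
        block_tasks = _phase_block_tasks(
            phase, condition, protocol, learner, rng,
            cl_sched, ea_cfg, phase_scores, error_source,
        )
        scores_by_width: dict[float, list] = {}
        for width in ([None] * phase.n_blocks if block_tasks is None else block_tasks):
            if block_tasks is None:  # curriculum: decided block by block
                width = cl_sched.next_block()
            task = ArcChannelTask(
                width=width,
                diameter=phase.diameter,
                movement_time=phase.movement_time,
                task_id=f"w{width:g}",
            )
            for trial in range(phase.trials_per_block):
                cur = skill(learner, width, counter.counts[float(width)])
                traj = generate_trajectory(learner, task, cur, rng)
                icf = compute_icf(traj, task)
                jerk = jerk_cost(traj, jerk_cfg)
                rmt = relative_movement_time(traj, task)
                counter.credit(width, cur)
                scores_by_width.setdefault(float(width), []).append(icf)
                if cl_sched is not None and phase.scheduler in ("calibration", "condition"):
                    cl_sched.observe(width, icf)
                rows.append(
                    (participant_id, condition, phase.name, block_counter, trial,
                     task.task_id, width, phase.diameter, phase.movement_time,
                     icf, jerk, rmt)
                )
            if cl_sched is not None and phase.scheduler == "condition":
                cl_sched.end_block()
            block_counter += 1
        phase_scores[phase.name] = scores_by_width

    frame = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "condition", "phase", "block_index", "trial_index",
            "task_id", "width", "diameter", "movement_time", "icf", "jerk",
            "relative_mt",
        ],
    )
    meta = {
        "condition": condition,
        "seed": int(seed),
        "participant_id": participant_id,
        "error_source": error_source,
        "jerk_config": {
            "window_length": jerk_cfg.window_length,
            "poly_order": jerk_cfg.poly_order,
            "deriv_order": jerk_cfg.deriv_order,
            "sample_rate": jerk_cfg.sample_rate,
        },
        "curriculum_config": {
            "gamma": cl_cfg.gamma, "beta": cl_cfg.beta, "eta": cl_cfg.eta,
            "d": cl_cfg.d, "init_weight": cl_cfg.init_weight,
        },
        "learner": {
            "score_noise_sd": learner.score_noise_sd,
            "radial_noise_floor_px": learner.radial_noise_floor_px,
            "radial_noise_ceil_px": learner.radial_noise_ceil_px,
            "noise_smooth_window": learner.noise_smooth_window,
            "timing_jitter_sd": learner.timing_jitter_sd,
            "transfer_coupling": learner.transfer_coupling,
            "sample_rate": learner.sample_rate,
        },
    }
    return SessionLog(frame, meta)


def run_cohort(
    condition: str,
    cohort: list[LearnerModel],
    seed: int,
    protocol: ExperimentProtocol | None = None,
    **kwargs,
) -> SessionLog:
    """Simulate every learner in a cohort under one condition.

    Session i uses seed ``seed + i``; participants are labeled p0, p1, ...
    so matched cohorts can be compared across conditions.
    """
    logs = [
        simulate_experiment(
            condition, learner, protocol, seed=seed + i,
            participant_id=f"p{i}", **kwargs,
        )
        for i, learner in enumerate(cohort)
    ]
    return SessionLog.concat(logs)


def _phase_block_tasks(
    phase,
    condition: str,
    protocol: ExperimentProtocol,
    learner: LearnerModel,
    rng: np.random.Generator,
    cl_sched,
    ea_cfg,
    phase_scores: dict,
    error_source: str,
):
    """Per-block width sequence for a phase; None means decide online (CL)."""
    if phase.scheduler == "fixed":
        return [phase.widths[0]] * phase.n_blocks
    if phase.scheduler == "calibration":
        order = list(phase.widths)
        perm = rng.permutation(len(order))
        return [order[i] for i in perm]
    # condition-scheduled training
    if condition == "curriculum":
        return None
    if condition == "random":
        return random_schedule(list(phase.widths), phase.n_blocks, rng)
    # error adaptation: one-shot allocation from the measured errors
    source = "calibration" if error_source == "calibration" else "pre_test"
    if source not in phase_scores:
        raise ValueError(
            f"error adaptation needs a {source!r} phase before training"
        )
    cal = phase_scores[source]
    if any(float(w) not in cal for w in phase.widths):
        raise ValueError(
            f"{source} phase did not cover all training widths; cannot "
            "compute error-adaptation allocation"
        )
    errors = _normalized_errors(cal, phase.widths)
    total = phase.n_blocks * phase.trials_per_block
    cfg = ea_cfg or EAConfig(total_trials=total)
    if cfg.total_trials != total:
        cfg = EAConfig(cfg.min_prop, cfg.max_prop, total)
    trial_counts = ea_allocate_trials(errors, cfg, block_size=phase.trials_per_block)
    block_counts = {
        w: int(c) // phase.trials_per_block for w, c in zip(phase.widths, trial_counts)
    }
    return ea_build_schedule(block_counts, rng)
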