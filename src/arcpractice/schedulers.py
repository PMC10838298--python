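"""Practice-scheduling conditions: curriculum-learning bandit, error
adaptation, and random baseline.

Three ways to order blocks of practice over the K = 7 training widths:

* **Curriculum learning (CL)** — a Multi-Armed Bandit whose reward is the
  learning progress on each task (absolute change in mean ICF between the
  last two practice windows of that task).  Tasks are drawn from a softmax
  over per-task weights, ``P_i = exp(w_i**gamma) / sum_j exp(w_j**gamma)``,
  and the chosen task's weight is updated as ``w_i <- beta*w_i + eta*r``.
  Progress fades as a task is mastered, so its weight decays and practice
  moves on.
* **Error adaptation (EA)** — a one-shot allocator: each task receives a
  number of trials proportional to its pre-assessed performance error,
  clamped between 7.15% and 36.3% of the total, then interleaved to avoid
  long same-task runs.
* **Random** — the contextual-interference baseline: a balanced pseudorandom
  shuffle with equal block counts per width.

All randomness flows through explicitly passed ``numpy.random.Generator``
instances; equal seeds give bit-identical schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "CurriculumConfig",
    "BanditState",
    "EAConfig",
    "softmax_task_distribution",
    "learning_progress_reward",
    "update_weight",
    "cl_next_task",
    "CurriculumScheduler",
    "ea_clamped_allocation",
    "ea_allocate_trials",
    "ea_build_schedule",
    "random_schedule",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class CurriculumConfig:
    """Curriculum-learning bandit parameters.

    gamma is the exploration exponent applied to the weight before
    exponentiation; beta and eta weigh the previous weight estimate and the
    fresh learning-progress reward; d is the reward window in trials (one
    4-trial block); init_weight seeds every arm.
    """

    gamma: float = 2.0
    beta: float = 0.5
    eta: float = 0.5
    d: int = 4
    init_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.beta < 0 or self.eta < 0:
            raise ValueError("beta and eta must be >= 0")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.init_weight < 0:
            raise ValueError("init_weight must be >= 0")


@dataclass
class BanditState:
    """Mutable bandit state: per-task weights, score histories, block count."""

    task_ids: list
    weights: np.ndarray
    history: dict
    t: int = 0

    @classmethod
    def initial(cls, task_ids: Sequence[Hashable], cfg: CurriculumConfig) -> "BanditState":
        if len(task_ids) < 1:
            raise ValueError("need at least one task")
        ids = list(task_ids)
        return cls(
            task_ids=ids,
            weights=np.full(len(ids), cfg.init_weight, dtype=float),
            history={tid: [] for tid in ids},
            t=0,
        )


def softmax_task_distribution(weights: np.ndarray, gamma: float) -> np.ndarray:
    """Task-selection probabilities P_i = exp(w_i^gamma) / sum_j exp(w_j^gamma).

    Strictly positive and summing to 1.  Weights must be nonnegative when
    gamma is non-integer (w^gamma would otherwise be complex).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape[0] < 1:
        raise ValueError("weights must be a nonempty 1-D array")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    if np.any(w < 0) and float(gamma) != int(gamma):
        raise ValueError("negative weight with non-integer gamma is undefined")
    z = np.power(w, gamma)
    z = z - np.max(z)  # overflow guard; softmax is shift-invariant
    e = np.exp(z)
    return e / np.sum(e)


def learning_progress_reward(history: Sequence[float], d: int) -> float:
    """Learning-progress reward: |mean(last d scores) - mean(previous d scores)|.

    Returns 0 while fewer than ``2 d`` scores exist for the task (the weight
    then decays until data accrues; calibration guarantees one block per task
    before training).
    """
    if d <= 0:
        raise ValueError("d must be positive")
    h = np.asarray(history, dtype=float)
    if h.shape[0] < 2 * d:
        return 0.0
    return float(abs(np.mean(h[-d:]) - np.mean(h[-2 * d : -d])))


def update_weight(w_i: float, r: float, cfg: CurriculumConfig) -> float:
    """Exponential-tracking weight update w_i' = beta*w_i + eta*r."""
    if not (np.isfinite(w_i) and np.isfinite(r)):
        raise ValueError("weight and reward must be finite")
    return cfg.beta * w_i + cfg.eta * r


def cl_next_task(state: BanditState, cfg: CurriculumConfig, rng: np.random.Generator):
    """Sample the next task from the softmax distribution; increments t."""
    if len(state.task_ids) < 1:
        raise ValueError("empty task set")
    p = softmax_task_distribution(state.weights, cfg.gamma)
    idx = int(rng.choice(len(state.task_ids), p=p))
    state.t += 1
    return state.task_ids[idx]


class CurriculumScheduler:
    """Online curriculum-learning scheduler over a fixed task set.

    Usage: call :meth:`next_block` to get the task for the next block, feed
    each trial's ICF back with :meth:`observe`, and call :meth:`end_block`
    after the block's trials to compute the reward and update the chosen
    task's weight.  Calibration scores can be pre-loaded with
    :meth:`observe` before training starts.
    """

    def __init__(
        self,
        task_ids: Sequence[Hashable],
        cfg: CurriculumConfig | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.cfg = cfg or CurriculumConfig()
        self.state = BanditState.initial(task_ids, self.cfg)
        self.rng = rng if rng is not None else np.random.default_rng()
        self._current: Hashable | None = None

    def next_block(self):
        self._current = cl_next_task(self.state, self.cfg, self.rng)
        return self._current

    def observe(self, task_id, icf: float) -> None:
        self.state.history[task_id].append(float(icf))

    def end_block(self) -> float:
        """Update the scheduled task's weight from its learning progress."""
        if self._current is None:
            raise RuntimeError("end_block called before next_block")
        r = learning_progress_reward(self.state.history[self._current], self.cfg.d)
        i = self.state.task_ids.index(self._current)
        self.state.weights[i] = update_weight(self.state.weights[i], r, self.cfg)
        self._current = None
        return r

    def probabilities(self) -> np.ndarray:
        return softmax_task_distribution(self.state.weights, self.cfg.gamma)


@dataclass(frozen=True)
class EAConfig:
    """Error-adaptation allocator bounds: per-task trial share is clamped to
    [min_prop, max_prop] of the total N (defaults 7.15% and 36.3%)."""

    min_prop: float = 0.0715
    max_prop: float = 0.363
    total_trials: int = 336

    def __post_init__(self) -> None:
        if not (0 < self.min_prop < self.max_prop < 1):
            raise ValueError("need 0 < min_prop < max_prop < 1")
        if self.total_trials < 1:
            raise ValueError("total_trials must be positive")


def _validate_errors(errors: np.ndarray, cfg: EAConfig) -> np.ndarray:
    e = np.asarray(errors, dtype=float)
    if e.ndim != 1 or e.shape[0] < 1:
        raise ValueError("errors must be a nonempty 1-D array")
    if np.any(e < 0):
        raise ValueError("errors must be nonnegative")
    if abs(e.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"errors must be normalized to sum 1, got {e.sum():.6f}")
    k = e.shape[0]
    if k * cfg.min_prop > 1 or k * cfg.max_prop < 1:
        raise ValueError("infeasible clamps: need K*min_prop <= 1 <= K*max_prop")
    return e


def ea_clamped_allocation(errors: np.ndarray, cfg: EAConfig) -> np.ndarray:
    """Pre-redistribution EA allocation: clamp(N*E_i, N*min_prop, N*max_prop).

    Returns the raw (float) per-task trial counts before they are adjusted
    to sum exactly to N.
    """
    e = _validate_errors(errors, cfg)
    n = cfg.total_trials
    return np.clip(n * e, n * cfg.min_prop, n * cfg.max_prop)


def _redistribute(raw: np.ndarray, errors: np.ndarray, cfg: EAConfig) -> np.ndarray:
    """Adjust clamped float counts to sum exactly to N, respecting clamps."""
    n = cfg.total_trials
    lo, hi = n * cfg.min_prop, n * cfg.max_prop
    out = raw.copy()
    for _ in range(len(out)):
        diff = n - out.sum()
        if abs(diff) < 1e-9:
            break
        if diff > 0:
            free = out < hi - 1e-12
            if not free.any():
                raise ValueError("cannot redistribute: all tasks at upper clamp")
            w = errors[free]
            w = w / w.sum() if w.sum() > 0 else np.full(w.shape, 1.0 / w.size)
            out[free] = np.minimum(out[free] + diff * w, hi)
        else:
            free = out > lo + 1e-12
            if not free.any():
                raise ValueError("cannot redistribute: all tasks at lower clamp")
            # remove proportionally to each free task's headroom above lo
            head = out[free] - lo
            out[free] = np.maximum(out[free] + diff * head / head.sum(), lo)
    return out


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative floats to integers summing to ``total``."""
    base = np.floor(raw).astype(int)
    deficit = total - int(base.sum())
    if deficit > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:deficit]] += 1
    return base


def ea_allocate_trials(
    errors: np.ndarray, cfg: EAConfig, block_size: int = 1
) -> np.ndarray:
    """Integer per-task trial counts N_i summing exactly to N.

    ``N_i = clamp(N*E_i, N*min_prop, N*max_prop)`` followed by
    redistribution of the excess/deficit (proportional to the unclamped
    tasks' errors when adding; see module docs) and largest-remainder
    rounding.  With ``block_size > 1`` the rounding is done at block
    granularity so each count is a whole number of blocks.
    """
    e = _validate_errors(errors, cfg)
    raw = ea_clamped_allocation(e, cfg)
    exact = _redistribute(raw, e, cfg)
    if block_size == 1:
        return _largest_remainder(exact, cfg.total_trials)
    if cfg.total_trials % block_size:
        raise ValueError("total_trials must be divisible by block_size")
    blocks = _largest_remainder(exact / block_size, cfg.total_trials // block_size)
    return blocks * block_size


def ea_build_schedule(counts: dict, rng: np.random.Generator) -> list:
    """Interleave per-task block counts, minimizing the longest same-task run.

    Greedy: at each step schedule the task with the most remaining blocks
    among those differing from the previous block (seeded-random tie-break);
    repeats only when forced.  Output contains each task exactly
    ``counts[task]`` times.
    """
    remaining = {t: int(c) for t, c in counts.items() if c > 0}
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be >= 0")
    if not remaining:
        raise ValueError("all counts are zero")
    order = sorted(remaining)  # deterministic base order before shuffling ties
    sequence: list = []
    prev = None
    while remaining:
        candidates = [t for t in order if t in remaining and t != prev]
        if not candidates:  # only the previous task remains
            candidates = [t for t in order if t in remaining]
        top = max(remaining[t] for t in candidates)
        best = [t for t in candidates if remaining[t] == top]
        pick = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
        sequence.append(pick)
        remaining[pick] -= 1
        if remaining[pick] == 0:
            del remaining[pick]
        prev = pick
    return sequence


def random_schedule(
    task_ids: Sequence[Hashable], n_blocks: int, rng: np.random.Generator
) -> list:
    """Balanced pseudorandom block order: each task n_blocks/K times."""
    k = len(task_ids)
    if k < 1:
        raise ValueError("empty task set")
    if n_blocks % k:
        raise ValueError(f"n_blocks={n_blocks} not divisible by K={k}")
    base = np.repeat(np.arange(k), n_blocks // k)
    perm = rng.permutation(base)
    return [task_ids[i] for i in perm]
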