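"""Derived quantities from session logs.

Learning rates are the OLS slopes of log-transformed per-block ICF or jerk
values against block index: an exponential learning curve y_b = A*exp(c*b)
is exactly log-linear, so the slope estimates the per-block rate c
(negative for improving jerk, positive for improving ICF).  Task switches
count the contextual interference a schedule induces.  Jerk variability is
the across-participant standard deviation of mean jerk, the homogeneity
measure of interest when comparing scheduling conditions.

Inferential statistics (ANOVA, post-hoc contrasts) are out of scope: the
tables produced here are tidy and ready for any standard stats package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .protocol_io import SessionLog

__all__ = [
    "LearningRate",
    "learning_rate",
    "switch_count",
    "jerk_variability",
    "phase_summary",
    "block_means",
    "per_participant_phase_means",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearningRate:
    """OLS fit of log(metric) on block index."""

    slope: float
    intercept: float
    stderr: float
    ci_low: float
    ci_high: float
    n_used: int
    n_dropped: int


def learning_rate(
    series: Sequence[float],
    metric: str = "icf",
    *,
    conf_level: float = 0.95,
) -> LearningRate:
    """Per-block learning rate: slope of log(value) versus block index.

    For ICF, blocks with value exactly 0 are dropped (with a logged count)
    since their log is undefined; negative values are an error.  For jerk —
    strictly positive by construction — any nonpositive value is an error.
    The confidence interval uses the usual t-based OLS slope interval.
    """
    if metric not in ("icf", "jerk"):
        raise ValueError("metric must be 'icf' or 'jerk'")
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be 1-D")
    x = np.arange(len(y), dtype=float)
    bad = np.flatnonzero(y < 0) if metric == "icf" else np.flatnonzero(y <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive {metric} values at blocks {bad.tolist()[:10]}"
        )
    n_dropped = 0
    if metric == "icf":
        keep = y > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("learning_rate: dropped %d zero-ICF blocks", n_dropped)
        x, y = x[keep], y[keep]
    if len(y) < 3:
        raise ValueError("need at least 3 positive values for a log-linear fit")
    fit = stats.linregress(x, np.log(y))
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, len(y) - 2)
    return LearningRate(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr),
        ci_low=float(fit.slope - tcrit * fit.stderr),
        ci_high=float(fit.slope + tcrit * fit.stderr),
        n_used=len(y),
        n_dropped=n_dropped,
    )


def switch_count(schedule: Sequence) -> int:
    """Number of consecutive block pairs whose tasks differ."""
    seq = list(schedule)
    if len(seq) < 1:
        raise ValueError("schedule must contain at least one block")
    return int(sum(a != b for a, b in zip(seq, seq[1:])))


def jerk_variability(per_participant_means: Sequence[float]) -> float:
    """Sample s.d. (n-1 denominator) of per-participant mean jerk."""
    vals = np.asarray(per_participant_means, dtype=float)
    if vals.ndim != 1 or vals.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    return float(np.std(vals, ddof=1))


def block_means(log: SessionLog, metric: str, phase: str = "training") -> pd.DataFrame:
    """Per (participant, block) mean of a metric within one phase.

    The natural input to :func:`learning_rate` — one row per block, in block
    order, per participant.
    """
    df = log.frame[log.frame["phase"] == phase]
    if df.empty:
        raise ValueError(f"no rows for phase {phase!r}")
    out = (
        df.groupby(["participant_id", "block_index"], as_index=False)[metric]
        .mean()
        .sort_values(["participant_id", "block_index"])
    )
    return out.reset_index(drop=True)


def per_participant_phase_means(log: SessionLog, metric: str = "jerk") -> pd.DataFrame:
    """Mean metric per (condition, phase, participant) — jerk_variability input."""
    return (
        log.frame.groupby(["condition", "phase", "participant_id"], as_index=False)[
            metric
        ].mean()
    )


def phase_summary(log: SessionLog) -> pd.DataFrame:
    """Tidy table of mean and s.d. of ICF and jerk per condition x phase.

    One row per (condition, phase, metric).  Cells with a single trial get
    s.d. 0.0 and are flagged via the ``n`` column.
    """
    if len(log) == 0:
        raise ValueError("empty session log")
    records = []
    for (cond, phase), grp in log.frame.groupby(["condition", "phase"], sort=False):
        for metric in ("icf", "jerk"):
            vals = grp[metric].to_numpy(dtype=float)
            records.append(
                {
                    "condition": cond,
                    "phase": phase,
                    "metric": metric,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    return pd.DataFrame.from_records(records)
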