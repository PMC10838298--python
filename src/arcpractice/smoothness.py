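"""Movement smoothness via the jerk cost.

Jerk is the third time-derivative of position.  Per the minimum-jerk account
of skilled movement, smoother (better-learned) movements have smaller
integrated squared jerk.  The per-trial jerk cost here is

    JERK = sum over interior samples of (j_x^2 + j_y^2),

where j_x, j_y are per-sample third-derivative estimates of the x and y
cursor coordinates obtained with a Savitzky-Golay filter (polynomial degree
3, derivative order 3).  Units are px^2 / s^6 summed over samples; the value
is comparable across trials recorded at the same rate and window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .task_geometry import Trajectory

__all__ = ["JerkConfig", "savgol_third_derivative", "jerk_cost"]

#: relative tolerance on sampling-interval uniformity
_UNIFORMITY_RTOL = 1e-3


@dataclass(frozen=True)
class JerkConfig:
    """Savitzky-Golay differentiation settings for the jerk cost.

    window_length must be odd and exceed poly_order; poly_order must be at
    least deriv_order (fixed at 3: the filter output *is* the jerk estimate).
    The default 21-sample window spans ~175 ms at 120 Hz.
    """

    window_length: int = 21
    poly_order: int = 3
    deriv_order: int = 3
    sample_rate: float = 120.0

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length <= self.poly_order:
            raise ValueError(
                "window_length must be odd and greater than poly_order, "
                f"got window_length={self.window_length}, poly_order={self.poly_order}"
            )
        if self.poly_order < self.deriv_order:
            raise ValueError("poly_order must be >= deriv_order")
        if self.deriv_order != 3:
            raise ValueError("deriv_order is fixed at 3 (jerk)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def half_window(self) -> int:
        return self.window_length // 2


def savgol_third_derivative(series: np.ndarray, cfg: JerkConfig) -> np.ndarray:
    """Per-sample third-derivative estimate of a uniformly sampled series.

    Returns values in (series units)/s^3.  Interior estimates (at least
    ``cfg.half_window`` samples from either end) are exact for polynomial
    inputs of degree <= ``cfg.poly_order``; edge estimates are
    polynomial-extrapolation artifacts and should be discarded by callers.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.shape[0] < cfg.window_length:
        raise ValueError(
            f"series length {x.shape[0]} shorter than window {cfg.window_length}"
        )
    return savgol_filter(
        x,
        window_length=cfg.window_length,
        polyorder=cfg.poly_order,
        deriv=cfg.deriv_order,
        delta=1.0 / cfg.sample_rate,
    )


def _check_uniform(timestamps: np.ndarray, cfg: JerkConfig) -> None:
    dt = np.diff(np.asarray(timestamps, dtype=float))
    expected = 1.0 / cfg.sample_rate
    if np.max(np.abs(dt - expected)) > _UNIFORMITY_RTOL * expected:
        raise ValueError(
            "trajectory is not uniformly sampled at "
            f"{cfg.sample_rate} Hz within tolerance"
        )


def jerk_cost(traj: Trajectory, cfg: JerkConfig | None = None) -> float:
    """Jerk cost of a trajectory: summed squared third derivatives, x and y.

    The first and last ``window_length // 2`` estimates are excluded — SG
    edge values extrapolate outside the data and would dominate the sum.
    Nonnegative; (near) zero only for motion whose third derivative vanishes
    in both dimensions, e.g. constant-velocity travel.
    """
    if cfg is None:
        cfg = JerkConfig()
    if len(traj) < cfg.window_length:
        raise ValueError(
            f"trajectory has {len(traj)} samples, needs >= {cfg.window_length}"
        )
    _check_uniform(traj.timestamps, cfg)
    jx = savgol_third_derivative(traj.points[:, 0], cfg)
    jy = savgol_third_derivative(traj.points[:, 1], cfg)
    h = cfg.half_window
    interior = slice(h, len(traj) - h)
    return float(np.sum(jx[interior] ** 2 + jy[interior] ** 2))
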