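"""Arc-channel steering task geometry and trajectory-level performance metrics.

The task asks a learner to steer a cursor along a semicircular channel of
width ``w`` whose centerline is the upper half of a circle of diameter ``D``
(the channel "length"), within a prescribed movement time ``MT``.  Performance
on a trial is summarized by the In-Channel Fraction (ICF): the proportion of
recorded cursor samples lying inside the channel, bounded in [0, 1].

Coordinate convention: continuous pixels, x rightward, y upward, origin at
the arc center (the midpoint between the start and end circles).  Screen
dumps with y growing downward can be converted with :func:`flip_y`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArcChannelTask",
    "Trajectory",
    "point_in_channel",
    "compute_icf",
    "relative_movement_time",
    "flip_y",
]


@dataclass(frozen=True)
class ArcChannelTask:
    """One steering task: channel width, diameter and movement time.

    Parameters
    ----------
    width : float
        Channel width ``w`` in px.  Narrower channels are nominally harder.
    diameter : float
        Channel diameter ``D`` in px; the centerline is the upper semicircle
        of radius ``D / 2``.
    movement_time : float
        Prescribed movement time ``MT`` in seconds.
    task_id : str
        Identifier; during training there is one task per width.
    """

    width: float
    diameter: float
    movement_time: float
    task_id: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.width) and self.width > 0):
            raise ValueError(f"width must be positive, got {self.width}")
        if not (np.isfinite(self.diameter) and self.diameter > self.width):
            raise ValueError(
                f"diameter must exceed width, got D={self.diameter}, w={self.width}"
            )
        if not (np.isfinite(self.movement_time) and self.movement_time > 0):
            raise ValueError(f"movement_time must be positive, got {self.movement_time}")

    @property
    def radius(self) -> float:
        """Centerline radius ``D / 2`` in px."""
        return self.diameter / 2.0


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 2-D cursor samples for one trial.

    ``timestamps`` are seconds, strictly increasing; ``points`` is an
    ``(n, 2)`` array of (x, y) pixel coordinates, y-up, origin at the arc
    center.
    """

    timestamps: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
        if ts.ndim != 1 or ts.shape[0] != pts.shape[0]:
            raise ValueError("timestamps and points must have equal length")
        if ts.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not np.all(np.isfinite(ts)) or not np.all(np.isfinite(pts)):
            raise ValueError("trajectory contains non-finite values")
        if not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


def _membership(points: np.ndarray, task: ArcChannelTask) -> np.ndarray:
    """Vectorized channel membership for an (n, 2) point array."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    x = pts[..., 0]
    y = pts[..., 1]
    r = np.hypot(x, y)
    radial_ok = np.abs(r - task.radius) <= task.width / 2.0
    # angular span [0, pi]: the upper half-plane, boundary inclusive
    angular_ok = y >= 0.0
    return radial_ok & angular_ok


def point_in_channel(point, task: ArcChannelTask) -> bool:
    """True iff ``point`` lies within the annular channel band.

    A point is in-channel when its radial deviation from the centerline
    radius ``D/2`` is at most ``w/2`` *and* its polar angle lies in the
    arc's span [0, pi].  Boundaries count as inside.
    """
    pt = np.asarray(point, dtype=float)
    if pt.shape != (2,):
        raise ValueError(f"point must be a 2-vector, got shape {pt.shape}")
    return bool(_membership(pt[np.newaxis, :], task)[0])


def compute_icf(traj: Trajectory, task: ArcChannelTask) -> float:
    """In-Channel Fraction: the proportion of samples inside the channel.

    A per-recorded-sample fraction in [0, 1]; 1 means the whole trial stayed
    in the channel, 0 means no sample did.
    """
    inside = _membership(traj.points, task)
    return float(np.mean(inside))


def relative_movement_time(traj: Trajectory, task: ArcChannelTask) -> float:
    """Trial duration divided by the prescribed movement time MT."""
    if task.movement_time <= 0:
        raise ValueError("movement_time must be positive")
    return traj.duration / task.movement_time


def flip_y(points: np.ndarray, screen_height: float = 0.0) -> np.ndarray:
    """Convert y-down screen coordinates to the y-up convention used here.

    With the default ``screen_height=0`` this simply negates y (origin
    already at the arc center); pass the screen height to also move the
    origin from the top edge.
    """
    pts = np.asarray(points, dtype=float).copy()
    pts[..., 1] = screen_height - pts[..., 1]
    return pts
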