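import math

import numpy as np
import pytest

from arcpractice import ArcChannelTask, Trajectory


@pytest.fixture
def test_task() -> ArcChannelTask:
    """The pre/post-test task: 18 px channel, 800 px diameter, MT 1 s."""
    return ArcChannelTask(width=18.0, diameter=800.0, movement_time=1.0, task_id="w18")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def arc_trajectory(
    task: ArcChannelTask,
    n: int = 121,
    radial_offset: float = 0.0,
    sample_rate: float = 120.0,
) -> Trajectory:
    """A uniform sweep of the upper semicircle at D/2 + radial_offset."""
    t = np.arange(n) / sample_rate
    theta = np.linspace(0.0, math.pi, n)
    r = task.radius + radial_offset
    pts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
    return Trajectory(timestamps=t, points=pts)


def brute_force_icf(traj: Trajectory, task: ArcChannelTask) -> float:
    """Independent per-point membership count (pure-python oracle)."""
    inside = 0
    for x, y in traj.points:
        dev = abs(math.hypot(x, y) - task.diameter / 2.0)
        if dev <= task.width / 2.0 and y >= 0.0:
            inside += 1
    return inside / len(traj.points)
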