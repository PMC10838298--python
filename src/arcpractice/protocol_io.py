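"""Experiment protocol declaration and session-log persistence.

The default protocol reproduces the two-day study design: on day 1 a
familiarization block (75 px channel), a 3-block pre-test on an 18 px
channel, a 7-block calibration sweep over the seven training widths, 84
training blocks of 4 trials scheduled by the assigned condition, and a
3-block post-test; on day 2 a 2-block retention test (12 trials per block)
and five 12-trial transfer blocks that vary channel diameter and movement
time while keeping the 18 px width.

Session logs are tidy per-trial tables persisted as CSV with a JSON sidecar
recording every configuration default and seed, so a run is reproducible
from its artifacts alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

__all__ = [
    "TRAINING_WIDTHS",
    "TEST_WIDTH",
    "PhaseSpec",
    "ExperimentProtocol",
    "default_protocol",
    "load_protocol",
    "SessionLog",
    "write_session_log",
    "read_session_log",
    "SESSION_LOG_COLUMNS",
]

#: the seven training channel widths, px
TRAINING_WIDTHS: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0)
#: pre-test / post-test / retention / transfer channel width, px
TEST_WIDTH: float = 18.0

_SCHEDULERS = ("fixed", "calibration", "condition")

SESSION_LOG_COLUMNS = [
    "participant_id",
    "condition",
    "phase",
    "block_index",
    "trial_index",
    "task_id",
    "width",
    "diameter",
    "movement_time",
    "icf",
    "jerk",
    "relative_mt",
]


@dataclass(frozen=True)
class PhaseSpec:
    """One experiment phase.

    ``scheduler`` is one of: ``fixed`` (every block uses ``widths[0]``),
    ``calibration`` (one block per width, seeded-shuffled order), or
    ``condition`` (block order decided by the participant's assigned
    scheduling condition over ``widths``).
    """

    name: str
    n_blocks: int
    trials_per_block: int
    widths: tuple[float, ...]
    diameter: float
    movement_time: float
    scheduler: str = "fixed"

    def __post_init__(self) -> None:
        problems = []
        if self.n_blocks < 1:
            problems.append(f"n_blocks={self.n_blocks}")
        if self.trials_per_block < 1:
            problems.append(f"trials_per_block={self.trials_per_block}")
        if not self.widths or any(w <= 0 for w in self.widths):
            problems.append(f"widths={self.widths}")
        if self.diameter <= max(self.widths, default=0):
            problems.append(f"diameter={self.diameter}")
        if self.movement_time <= 0:
            problems.append(f"movement_time={self.movement_time}")
        if self.scheduler not in _SCHEDULERS:
            problems.append(f"scheduler={self.scheduler!r} (known: {_SCHEDULERS})")
        if self.scheduler == "calibration" and self.n_blocks != len(self.widths):
            problems.append(
                f"calibration needs n_blocks == len(widths), got {self.n_blocks}"
            )
        if problems:
            raise ValueError(f"invalid phase {self.name!r}: " + ", ".join(problems))


@dataclass(frozen=True)
class ExperimentProtocol:
    """Ordered phases of one participant's full session."""

    phases: tuple[PhaseSpec, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol has no phases")

    @property
    def training_widths(self) -> tuple[float, ...]:
        for ph in self.phases:
            if ph.scheduler == "condition":
                return ph.widths
        return TRAINING_WIDTHS

    @property
    def all_widths(self) -> tuple[float, ...]:
        seen: list[float] = []
        for ph in self.phases:
            for w in ph.widths:
                if w not in seen:
                    seen.append(w)
        return tuple(sorted(seen))


def default_protocol() -> ExperimentProtocol:
    """The built-in two-day protocol (block and trial counts as published)."""
    phases = [
        PhaseSpec("familiarization", 1, 4, (75.0,), 800.0, 1.0, "fixed"),
        PhaseSpec("pre_test", 3, 4, (TEST_WIDTH,), 800.0, 1.0, "fixed"),
        PhaseSpec("calibration", 7, 4, TRAINING_WIDTHS, 800.0, 1.0, "calibration"),
        PhaseSpec("training", 84, 4, TRAINING_WIDTHS, 800.0, 1.0, "condition"),
        PhaseSpec("post_test", 3, 4, (TEST_WIDTH,), 800.0, 1.0, "fixed"),
        PhaseSpec("retention", 2, 12, (TEST_WIDTH,), 800.0, 1.0, "fixed"),
        PhaseSpec("transfer_1", 1, 12, (TEST_WIDTH,), 600.0, 1.0, "fixed"),
        PhaseSpec("transfer_2", 1, 12, (TEST_WIDTH,), 400.0, 1.0, "fixed"),
        PhaseSpec("transfer_3", 1, 12, (TEST_WIDTH,), 800.0, 0.7, "fixed"),
        PhaseSpec("transfer_4", 1, 12, (TEST_WIDTH,), 600.0, 0.7, "fixed"),
        PhaseSpec("transfer_5", 1, 12, (TEST_WIDTH,), 400.0, 0.7, "fixed"),
    ]
    return ExperimentProtocol(tuple(phases))


def load_protocol(document: str | dict | Path | None = None) -> ExperimentProtocol:
    """Build a validated protocol from a YAML document, mapping, or path.

    An empty/missing document yields :func:`default_protocol`.  Each phase
    mapping accepts: name, n_blocks, trials_per_block, width or widths,
    diameter, movement_time, scheduler.
    """
    if document is None:
        return default_protocol()
    if isinstance(document, Path):
        document = document.read_text()
    if isinstance(document, str):
        document = yaml.safe_load(document)
    if not document:
        return default_protocol()
    if not isinstance(document, dict) or "phases" not in document:
        raise ValueError("protocol document must be a mapping with a 'phases' list")
    phases = []
    for i, raw in enumerate(document["phases"]):
        if not isinstance(raw, dict):
            raise ValueError(f"phase #{i} is not a mapping")
        raw = dict(raw)
        if "width" in raw and "widths" not in raw:
            raw["widths"] = [raw.pop("width")]
        unknown = set(raw) - {
            "name", "n_blocks", "trials_per_block", "widths",
            "diameter", "movement_time", "scheduler",
        }
        if unknown:
            raise ValueError(f"phase #{i}: unknown fields {sorted(unknown)}")
        try:
            phases.append(
                PhaseSpec(
                    name=str(raw["name"]),
                    n_blocks=int(raw["n_blocks"]),
                    trials_per_block=int(raw["trials_per_block"]),
                    widths=tuple(float(w) for w in raw["widths"]),
                    diameter=float(raw["diameter"]),
                    movement_time=float(raw["movement_time"]),
                    scheduler=str(raw.get("scheduler", "fixed")),
                )
            )
        except KeyError as exc:
            raise ValueError(f"phase #{i}: missing field {exc}") from exc
    return ExperimentProtocol(tuple(phases))


@dataclass
class SessionLog:
    """Per-trial record of one or more simulated (or imported) sessions.

    ``frame`` holds one row per trial with :data:`SESSION_LOG_COLUMNS`;
    ``meta`` records the configs and seeds that produced it.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SESSION_LOG_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"session log missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @staticmethod
    def concat(logs: Sequence["SessionLog"]) -> "SessionLog":
        frame = pd.concat([lg.frame for lg in logs], ignore_index=True)
        meta = {"sessions": [lg.meta for lg in logs]}
        return SessionLog(frame, meta)


def write_session_log(log: SessionLog, path: str | Path) -> Path:
    """Write the log as CSV plus a ``<stem>.meta.json`` sidecar of configs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    log.frame.to_csv(path, index=False, columns=SESSION_LOG_COLUMNS)
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(log.meta, indent=2, default=str))
    return path


def read_session_log(path: str | Path) -> SessionLog:
    """Read a CSV session log (and its JSON sidecar if present)."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in SESSION_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: schema mismatch, missing columns {missing}")
    sidecar = path.with_suffix(".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SessionLog(frame, meta)
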