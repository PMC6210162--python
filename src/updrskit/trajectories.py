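"""Core containers: per-finger 3D trajectories and task recordings.

All positions are in millimetres in a right-handed camera frame
(X right, Y up, Z toward the scene); time is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

FINGERS = ("thumb", "index", "middle", "ring", "pinky")
PALM = "palm"


class TaskKind(str, Enum):
    """The three upper-limb UPDRS motor tasks (Part III items 3.4-3.6)."""

    FT = "FT"  # finger tapping: thumb-index aperture
    OC = "OC"  # hand opening-closing: fingers-to-palm aperture
    PS = "PS"  # pronation-supination: hand rotation angle

    @classmethod
    def coerce(cls, value) -> "TaskKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(f"unknown task kind: {value!r}") from None


@dataclass
class FingertipTrajectory:
    """Timestamped 3D positions (mm) of a single finger/landmark."""

    finger: str
    t: np.ndarray          # (n,) seconds, strictly increasing
    xyz: np.ndarray        # (n, 3) mm

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise ValueError("trajectory requires t of shape (n,) and xyz of shape (n, 3)")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError(f"timestamps of finger {self.finger!r} are not strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


@dataclass
class TaskRecording:
    """One task performance: a set of fingertip trajectories plus metadata.

    ``label`` is the clinician UPDRS class (0-3) when known; ``cohort`` is
    "PD" or "HC".  ``ground_truth`` carries the simulator's per-cycle table
    when the recording is synthetic.
    """

    task: TaskKind
    trajectories: dict[str, FingertipTrajectory]
    hand: str = "R"
    label: int | None = None
    cohort: str | None = None
    ground_truth: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.task = TaskKind.coerce(self.task)
        if self.label is not None:
            self.label = int(self.label)

    def __getitem__(self, finger: str) -> FingertipTrajectory:
        try:
            return self.trajectories[finger]
        except KeyError:
            raise KeyError(
                f"recording has no trajectory for finger {finger!r} "
                f"(available: {sorted(self.trajectories)})"
            ) from None

    def fingers(self) -> list[str]:
        return sorted(self.trajectories)
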