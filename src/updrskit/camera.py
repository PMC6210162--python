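"""Pinhole camera model and 2D<->3D re-projection.

Image convention: origin top-left, u right, v down.  World frame: X right,
Y up, Z toward the scene — hence Y = (cy - v) * z / fy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np


@dataclass(frozen=True)
class CameraModel:
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    depth_scale: float = 1.0   # mm per stored depth unit

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def project(self, xyz: np.ndarray) -> np.ndarray:
        """3D points (n, 3) mm -> pixel coordinates (n, 2) as (u, v)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        z = xyz[:, 2]
        if np.any(z <= 0):
            raise ValueError("cannot project points at non-positive depth")
        u = self.cx + xyz[:, 0] * self.fx / z
        v = self.cy - xyz[:, 1] * self.fy / z
        return np.column_stack([u, v])

    def backproject(self, u, v, z_mm) -> np.ndarray:
        """Pixels plus metric depth -> 3D points (n, 3) mm."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        z = np.atleast_1d(np.asarray(z_mm, dtype=float))
        x = (u - self.cx) * z / self.fx
        y = (self.cy - v) * z / self.fy
        return np.column_stack([x, y, z])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CameraModel":
        with open(path) as fh:
            return cls(**json.load(fh))


#: Default model loosely matching a 640x480 short-range RGB-D depth stream.
DEFAULT_CAMERA = CameraModel(fx=600.0, fy=600.0, cx=320.0, cy=240.0, width=640, height=480)
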