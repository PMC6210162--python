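"""Trajectory-comparison framework for validating hand trackers.

Implements the accuracy statistics used to compare a tracker under test
against a gold-standard reference capture of the same movement: per-sample
Euclidean distances ``d_i`` between time-aligned positions, summarised as
``D_MEAN`` (mean), ``SD`` (standard deviation) and ``MAD`` (maximum absolute
difference), after optional removal of the mean offset vector ``d̄`` —
device-dependent constant translations are irrelevant when only the movement
matters.  Supporting steps: rigid (Kabsch) calibration alignment between
device frames, cubic-spline resampling to a common uniform rate, and masking
to the devices' common working volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .trajectories import FingertipTrajectory

__all__ = [
    "RigidTransform",
    "AccuracyReport",
    "WorkingVolume",
    "BoxVolume",
    "FrustumVolume",
    "estimate_rigid_transform",
    "estimate_time_lag",
    "resample_trajectory",
    "compare_trajectories",
    "aggregate_reports",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x -> R @ x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray
    rms: float = 0.0   # residual RMS of the fit that produced it, mm

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (R^T R = I within 1e-9)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def estimate_rigid_transform(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rotation + translation aligning paired points (Kabsch).

    No scaling is estimated.  Requires at least 3 non-collinear pairs;
    collinear or otherwise rank-deficient configurations leave the rotation
    about the point axis unconstrained and are rejected.
    """
    src = np.asarray(source, dtype=float)
    dst = np.asarray(target, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must both be (n, 3)")
    if src.shape[0] < 3:
        raise ValueError("at least 3 point pairs are required")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    s_c, d_c = src - mu_s, dst - mu_d
    H = s_c.T @ d_c
    U, S, Vt = np.linalg.svd(H)
    scale = np.linalg.norm(s_c) * np.linalg.norm(d_c)
    if scale == 0 or S[1] <= 1e-9 * S[0]:
        raise ValueError(
            "degenerate point configuration: points are collinear or coincident "
            "(cross-covariance rank < 2), rotation is not identifiable")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    resid = dst - (src @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(R, t, rms=rms)


def resample_trajectory(traj: FingertipTrajectory, rate: float = 100.0) -> FingertipTrajectory:
    """Cubic-spline resampling of a trajectory onto a uniform grid.

    The grid spans the input time window only (no extrapolation).  Default
    100 samples/s, the common rate used when comparing devices with
    different native rates.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t, xyz = traj.t, traj.xyz
    if t.size < 4:
        raise ValueError("cubic-spline resampling needs at least 4 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing (duplicates present)")
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * rate)) + 1) / rate
    spl = CubicSpline(t, xyz, axis=0)
    return FingertipTrajectory(traj.finger, grid, spl(grid))


# ---------------------------------------------------------------------------
# working volumes
# ---------------------------------------------------------------------------

class WorkingVolume:
    """Spatial region where a device's measurements are considered reliable."""

    def contains(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class BoxVolume(WorkingVolume):
    """Axis-aligned box in the device frame, mm."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self):
        if not np.all(np.asarray(self.hi) > np.asarray(self.lo)):
            raise ValueError("box must have a nonempty interior")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)


@dataclass(frozen=True)
class FrustumVolume(WorkingVolume):
    """Truncated viewing pyramid: near/far depth planes plus a linear lateral
    bound growing with depth (|x|, |y| <= tan(half-angle) * z)."""

    z_near: float
    z_far: float
    tan_half_x: float = 0.5
    tan_half_y: float = 0.4

    def __post_init__(self):
        if not 0 < self.z_near < self.z_far:
            raise ValueError("require 0 < z_near < z_far")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        z = p[:, 2]
        return ((z >= self.z_near) & (z <= self.z_far)
                & (np.abs(p[:, 0]) <= self.tan_half_x * z)
                & (np.abs(p[:, 1]) <= self.tan_half_y * z))


# ---------------------------------------------------------------------------
# accuracy statistics
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """D_MEAN / SD / MAD of per-sample distances for one trajectory pair,
    plus the mean offset vector that was (or could be) removed."""

    d_mean: float
    sd: float
    mad: float
    offset: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)

    def to_dict(self) -> dict:
        return {"d_mean_mm": self.d_mean, "sd_mm": self.sd, "mad_mm": self.mad,
                "offset_mm": self.offset.tolist(), "n_samples": self.n_samples}


def compare_trajectories(test: FingertipTrajectory,
                         reference: FingertipTrajectory,
                         transform: RigidTransform | None = None,
                         volume: WorkingVolume | None = None,
                         remove_offset: bool = True,
                         scalar_offset: bool = False,
                         ddof: int = 0,
                         return_residuals: bool = False):
    """Offset-corrected accuracy statistics between a test and a reference
    trajectory sampled on the same uniform grid.

    The test trajectory is first mapped into the reference frame by
    ``transform`` (calibration), then samples whose *reference* position
    falls outside ``volume`` are discarded.  Residual vectors
    ``r_i = y_i - x_i`` have their mean vector d̄ subtracted when
    ``remove_offset`` (vector mode; ``scalar_offset`` instead subtracts the
    mean of the scalar distances from the ``d_i`` sequence).  Reported:
    D_MEAN = mean(d_i), SD = std(d_i) (population convention by default,
    ``ddof`` configurable), MAD = max(d_i).
    """
    if test.t.size != reference.t.size or not np.allclose(test.t, reference.t, atol=1e-9):
        raise ValueError("trajectories must share a common uniform time grid; "
                         "resample both to the same rate first")
    x = transform.apply(test.xyz) if transform is not None else test.xyz
    y = reference.xyz
    keep = volume.contains(y) if volume is not None else np.ones(len(y), bool)
    if not np.any(keep):
        raise ValueError("no overlapping samples inside the working volume")
    r = y[keep] - x[keep]
    offset = r.mean(axis=0)
    if remove_offset and not scalar_offset:
        r = r - offset
    d = np.linalg.norm(r, axis=1)
    if remove_offset and scalar_offset:
        d = np.abs(d - d.mean())
    report = AccuracyReport(d_mean=float(d.mean()),
                            sd=float(d.std(ddof=ddof)),
                            mad=float(d.max()),
                            offset=offset,
                            n_samples=int(keep.sum()))
    if return_residuals:
        return report, d
    return report


def estimate_time_lag(test: FingertipTrajectory, reference: FingertipTrajectory,
                      rate: float, max_lag_s: float = 0.2) -> float:
    """Residual clock offset between two co-captured trajectories, seconds.

    Cross-correlates the centred speed profiles (norm of the per-sample
    velocity) within +/-``max_lag_s`` and returns the lag that maximizes the
    correlation: positive means the test trajectory lags the reference.
    Off the main comparison path by default — devices are assumed
    clock-synchronized in this package's scope; real co-captures can apply
    the returned lag before :func:`compare_trajectories`.
    """
    def speed(tr):
        v = np.linalg.norm(np.diff(tr.xyz, axis=0), axis=1) * rate
        return v - v.mean()

    a, b = speed(test), speed(reference)
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    max_shift = int(round(max_lag_s * rate))
    best_lag, best_corr = 0, -np.inf
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            x, y = a[shift:], b[: n - shift]
        else:
            x, y = a[: n + shift], b[-shift:]
        if x.size < 4:
            continue
        c = float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y) + 1e-30))
        if c > best_corr:
            best_corr, best_lag = c, shift
    return best_lag / rate


def aggregate_reports(reports: list[AccuracyReport]) -> AccuracyReport:
    """Device-level accuracy over a set of trajectory comparisons:
    D_MEAN and SD averaged across trajectories, MAD as the maximum over them."""
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    return AccuracyReport(
        d_mean=float(np.mean([r.d_mean for r in reports])),
        sd=float(np.mean([r.sd for r in reports])),
        mad=float(np.max([r.mad for r in reports])),
        offset=np.mean([r.offset for r in reports], axis=0),
        n_samples=int(np.sum([r.n_samples for r in reports])),
    )
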