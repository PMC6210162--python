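"""Colour-marker hand tracking on RGB-D frame sequences.

Re-implements the glove-tracking pipeline: depth-based hand segmentation
(the hand is the depth blob closest to the camera), lighting classification
from the white palm marker with HSV colour-constancy scaling, per-colour HSV
threshold segmentation of the fingertip markers, CamShift tracking
(mean-shift on a hue back-projection with an adaptive window) for robustness
across frames, and pinhole re-projection of marker pixels plus depth to 3D
fingertip positions.

Image convention: origin top-left, u right, v down; the world frame is Y-up
(see :mod:`updrskit.camera`).  All depth images are metric (mm per unit
times the camera's ``depth_scale``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.measure import label, regionprops
from skimage.transform import hough_circle, hough_circle_peaks

from .camera import CameraModel
from .trajectories import FingertipTrajectory

log = logging.getLogger(__name__)

__all__ = [
    "LightingCondition",
    "HSVTriplet",
    "MarkerObservation",
    "HandSegmentation",
    "NoHandDetectedError",
    "default_triplets",
    "segment_hand",
    "classify_lighting",
    "detect_palm_marker",
    "segment_markers",
    "track_markers",
    "reproject",
    "observations_to_trajectories",
]

MIN_BLOB_AREA = 10  # px


class NoHandDetectedError(ValueError):
    """Depth frame contains no valid (positive) depth pixels."""


class LightingCondition(str, Enum):
    LOW = "low"
    NORMAL = "normal"
    HIGH = "high"


@dataclass(frozen=True)
class HSVTriplet:
    """Per-channel (low, high) segmentation bounds, all in [0, 1].

    The thresholds are lighting-condition specific: a tracker deployment
    calibrates one triplet per marker colour per lighting condition.
    """

    h: tuple[float, float]
    s: tuple[float, float]
    v: tuple[float, float]
    lighting: LightingCondition = LightingCondition.NORMAL

    def __post_init__(self):
        for lo, hi in (self.h, self.s, self.v):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("HSV bounds must satisfy 0 <= low <= high <= 1")

    def mask(self, hsv: np.ndarray) -> np.ndarray:
        return ((hsv[..., 0] >= self.h[0]) & (hsv[..., 0] <= self.h[1])
                & (hsv[..., 1] >= self.s[0]) & (hsv[..., 1] <= self.s[1])
                & (hsv[..., 2] >= self.v[0]) & (hsv[..., 2] <= self.v[1]))


def default_triplets(marker_hues_deg: dict[str, float],
                     hue_halfwidth: float = 0.05,
                     lighting: LightingCondition = LightingCondition.NORMAL
                     ) -> dict[str, HSVTriplet]:
    """Sensible default triplets for saturated primary-colour markers.

    Real footage needs experimentally calibrated triplets per lighting
    condition; these defaults suit the synthetic renderer and well-lit
    saturated markers only.
    """
    out = {}
    for name, hue in marker_hues_deg.items():
        h = hue / 360.0
        out[name] = HSVTriplet(h=(max(0.0, h - hue_halfwidth), min(1.0, h + hue_halfwidth)),
                               s=(0.4, 1.0), v=(0.25, 1.0), lighting=lighting)
    return out


# ---------------------------------------------------------------------------
# hand segmentation and lighting
# ---------------------------------------------------------------------------

@dataclass
class HandSegmentation:
    centroid_mm: np.ndarray          # 3D, camera frame
    bbox_2d: tuple[int, int, int, int]   # (vmin, umin, vmax, umax)
    bbox_3d: tuple[np.ndarray, np.ndarray]
    mask: np.ndarray                 # bool, hand pixels


def segment_hand(depth: np.ndarray, camera: CameraModel,
                 band_mm: float = 150.0) -> HandSegmentation:
    """Segment the hand as the depth points nearest the camera.

    All valid pixels within ``band_mm`` of the closest valid depth form the
    hand mask (a hand spans roughly 150 mm in depth); the centroid is the
    mean of their re-projected 3D points.
    """
    z = np.asarray(depth, dtype=float) * camera.depth_scale
    valid = z > 0
    if not valid.any():
        raise NoHandDetectedError("no valid depth pixels: no hand in view")
    z_near = z[valid].min()
    mask = valid & (z <= z_near + band_mm)
    vv, uu = np.nonzero(mask)
    pts = camera.backproject(uu, vv, z[mask])
    centroid = pts.mean(axis=0)
    bbox_2d = (int(vv.min()), int(uu.min()), int(vv.max()), int(uu.max()))
    return HandSegmentation(centroid_mm=centroid, bbox_2d=bbox_2d,
                            bbox_3d=(pts.min(axis=0), pts.max(axis=0)), mask=mask)


@dataclass
class LightingResult:
    condition: LightingCondition
    scales: tuple[float, float, float]   # multiplicative H, S, V correction


def classify_lighting(palm_hsv: np.ndarray,
                      reference_v: float = 0.95,
                      reference_hs: tuple[float, float] = (0.0, 0.0),
                      thresholds: tuple[float, float] | None = None) -> LightingResult:
    """Classify ambient lighting from the white palm marker region and derive
    colour-constancy scale factors.

    The mean V of the (nominally white) marker is compared against two
    thresholds — by default the tertile split of the reference V — giving
    low / normal / high; per-channel scale factors map the observed mean
    H, S, V toward the reference values so the video sub-streams can be
    rescaled before thresholding.
    """
    region = np.asarray(palm_hsv, dtype=float).reshape(-1, 3)
    if region.size == 0:
        raise ValueError("palm marker region is empty")
    mean_h, mean_s, mean_v = region.mean(axis=0)
    if thresholds is None:
        thresholds = (reference_v * 2.0 / 3.0, reference_v * 4.0 / 3.0)
    if mean_v < thresholds[0]:
        cond = LightingCondition.LOW
    elif mean_v > min(thresholds[1], 1.0 - 1e-9):
        cond = LightingCondition.HIGH
    else:
        cond = LightingCondition.NORMAL
    ref_h, ref_s = reference_hs
    scale_h = ref_h / mean_h if mean_h > 0 and ref_h > 0 else 1.0
    scale_s = ref_s / mean_s if mean_s > 0 and ref_s > 0 else 1.0
    scale_v = reference_v / mean_v if mean_v > 0 else 1.0
    return LightingResult(condition=cond, scales=(scale_h, scale_s, scale_v))


def detect_palm_marker(frame: np.ndarray, radius_range: tuple[int, int] = (6, 20),
                       bbox: tuple[int, int, int, int] | None = None,
                       accum_threshold: float = 0.4):
    """Find the white circular palm marker by a circular Hough transform.

    ``frame`` is a grayscale/V-channel image in [0, 1].  Detection is
    restricted to ``bbox`` (the hand bounding box) when given; returns
    (center_u, center_v, radius) of the strongest accumulator peak, or None
    when no circle clears ``accum_threshold``.
    """
    img = np.asarray(frame, dtype=float)
    v0 = u0 = 0
    if bbox is not None:
        vmin, umin, vmax, umax = bbox
        img = img[vmin:vmax + 1, umin:umax + 1]
        v0, u0 = vmin, umin
    if img.size == 0 or img.max() == img.min():
        return None
    edges = canny(img, sigma=1.5)
    radii = np.arange(radius_range[0], radius_range[1] + 1)
    h = hough_circle(edges, radii)
    accums, cu, cv, r = hough_circle_peaks(h, radii, total_num_peaks=1)
    if accums.size == 0 or accums[0] < accum_threshold:
        return None
    return (float(cu[0] + u0), float(cv[0] + v0), float(r[0]))


# ---------------------------------------------------------------------------
# marker segmentation, CamShift, re-projection
# ---------------------------------------------------------------------------

@dataclass
class Blob:
    centroid_uv: tuple[float, float]
    area: int
    pixels: tuple[np.ndarray, np.ndarray]   # (v indices, u indices)


def segment_markers(hsv: np.ndarray, triplets: dict[str, HSVTriplet],
                    hand_mask: np.ndarray | None = None,
                    min_area: int = MIN_BLOB_AREA) -> dict[str, list[Blob]]:
    """Connected colour blobs per marker within the HSV thresholds and mask."""
    out: dict[str, list[Blob]] = {}
    for name, trip in triplets.items():
        m = trip.mask(hsv)
        if hand_mask is not None:
            m &= hand_mask
        blobs = []
        for prop in regionprops(label(m)):
            if prop.area < min_area:
                continue
            vv, uu = prop.coords[:, 0], prop.coords[:, 1]
            blobs.append(Blob(centroid_uv=(float(uu.mean()), float(vv.mean())),
                              area=int(prop.area), pixels=(vv, uu)))
        if not blobs:
            log.info("no blob found for marker %r", name)
        out[name] = blobs
    return out


def _camshift(prob: np.ndarray, window: tuple[int, int, int, int],
              n_iter: int = 15, eps: float = 0.5) -> tuple[int, int, int, int] | None:
    """CamShift: mean-shift of a window over a back-projection image with
    window size adapted from the zeroth moment.  Window is (vmin, umin,
    vmax, umax); returns the converged window or None when the window
    contains no probability mass."""
    h, w = prob.shape
    vmin, umin, vmax, umax = window
    for _ in range(n_iter):
        vmin, umin = max(0, vmin), max(0, umin)
        vmax, umax = min(h - 1, vmax), min(w - 1, umax)
        roi = prob[vmin:vmax + 1, umin:umax + 1]
        m00 = roi.sum()
        if m00 <= 0:
            return None
        vv, uu = np.mgrid[vmin:vmax + 1, umin:umax + 1]
        cv_ = (roi * vv).sum() / m00
        cu = (roi * uu).sum() / m00
        # adapt size: side ~ 2 * sqrt(mass), the classic CamShift rule for a
        # roughly uniform blob on a clean background
        s = max(4.0, 2.0 * np.sqrt(m00))
        n_vmin, n_vmax = int(round(cv_ - s / 2)), int(round(cv_ + s / 2))
        n_umin, n_umax = int(round(cu - s / 2)), int(round(cu + s / 2))
        moved = abs(n_vmin - vmin) + abs(n_umin - umin)
        vmin, umin, vmax, umax = n_vmin, n_umin, n_vmax, n_umax
        if moved < eps:
            break
    return (max(0, vmin), max(0, umin), min(h - 1, vmax), min(w - 1, umax))


def _hue_histogram(hsv: np.ndarray, pixels, n_bins: int = 32) -> np.ndarray:
    hues = hsv[pixels[0], pixels[1], 0]
    hist, _ = np.histogram(hues, bins=n_bins, range=(0.0, 1.0))
    hist = hist.astype(float)
    return hist / hist.max() if hist.max() > 0 else hist


def _backproject(hsv: np.ndarray, hist: np.ndarray, s_min: float = 0.3,
                 v_min: float = 0.2) -> np.ndarray:
    n_bins = hist.size
    bins = np.minimum((hsv[..., 0] * n_bins).astype(int), n_bins - 1)
    prob = hist[bins]
    prob[(hsv[..., 1] < s_min) | (hsv[..., 2] < v_min)] = 0.0
    return prob


@dataclass
class MarkerObservation:
    frame: int
    marker: str
    centroid_uv: tuple[float, float]
    centroid_mm: np.ndarray
    pixel_count: int

    def __post_init__(self):
        if self.pixel_count < MIN_BLOB_AREA:
            raise ValueError("observation below minimum blob size")
        if self.centroid_mm[2] <= 0:
            raise ValueError("observation depth must be positive")


def reproject(pixels, depth: np.ndarray, camera: CameraModel) -> np.ndarray | None:
    """Mean 3D position (mm) of blob pixels with valid depth, or None.

    X = (u - cx) z / fx, Y = (cy - v) z / fy, Z = z.
    """
    vv, uu = pixels
    z = np.asarray(depth, dtype=float)[vv, uu] * camera.depth_scale
    ok = z > 0
    if not ok.any():
        return None
    pts = camera.backproject(uu[ok], vv[ok], z[ok])
    return pts.mean(axis=0)


def _nearest_blob(blobs: list[Blob], center: tuple[float, float]) -> Blob:
    d = [np.hypot(b.centroid_uv[0] - center[0], b.centroid_uv[1] - center[1]) for b in blobs]
    return blobs[int(np.argmin(d))]


def track_markers(frames, camera: CameraModel,
                  triplets: dict[str, HSVTriplet] | None = None,
                  marker_hues_deg: dict[str, float] | None = None,
                  times: np.ndarray | None = None,
                  max_lost: int = 10,
                  min_area: int = MIN_BLOB_AREA) -> dict[str, list[MarkerObservation | None]]:
    """Track every colour marker over an RGB-D frame sequence.

    Per frame: segment the hand from depth, back-project each marker's hue
    histogram and run CamShift from its previous window, then take the
    centroid of the threshold-segmented blob inside the converged window.
    A marker whose window loses all probability mass is re-seeded from a
    fresh whole-frame segmentation (nearest blob to the last known
    position); when that also fails the frame is recorded as a gap (None) —
    positions are never fabricated.  Deterministic: identical input yields
    identical output.
    """
    if triplets is None:
        if marker_hues_deg is None:
            from .synthetic import MARKER_COLORS
            marker_hues_deg = MARKER_COLORS
        triplets = default_triplets(marker_hues_deg)
    obs: dict[str, list[MarkerObservation | None]] = {m: [] for m in triplets}
    windows: dict[str, tuple[int, int, int, int] | None] = {m: None for m in triplets}
    hists: dict[str, np.ndarray | None] = {m: None for m in triplets}
    last_uv: dict[str, tuple[float, float] | None] = {m: None for m in triplets}
    lost: dict[str, int] = {m: 0 for m in triplets}

    for fi, frame in enumerate(frames):
        rgb, depth = frame.rgb, frame.depth
        idx = getattr(frame, "index", fi)
        hsv = rgb2hsv(rgb)
        try:
            hand = segment_hand(depth, camera)
            mask = hand.mask
        except NoHandDetectedError:
            for m in triplets:
                obs[m].append(None)
            continue
        segments = None   # lazily computed whole-frame segmentation
        for m, trip in triplets.items():
            blob = None
            if windows[m] is not None and hists[m] is not None and lost[m] <= max_lost:
                prob = _backproject(hsv, hists[m])
                win = _camshift(prob, windows[m])
                if win is not None:
                    vmin, umin, vmax, umax = win
                    wmask = np.zeros_like(mask)
                    wmask[vmin:vmax + 1, umin:umax + 1] = True
                    local = segment_markers(hsv, {m: trip}, mask & wmask, min_area)[m]
                    if local:
                        blob = _nearest_blob(local, last_uv[m]) if last_uv[m] else local[0]
            if blob is None:
                # lost (or first frame): re-seed from fresh segmentation
                if segments is None:
                    segments = segment_markers(hsv, triplets, mask, min_area)
                cand = segments[m]
                if cand:
                    blob = (_nearest_blob(cand, last_uv[m]) if last_uv[m] else
                            max(cand, key=lambda b: b.area))
            if blob is None:
                obs[m].append(None)
                lost[m] += 1
                continue
            centroid3d = reproject(blob.pixels, depth, camera)
            if centroid3d is None:
                obs[m].append(None)
                lost[m] += 1
                continue
            cu, cv_ = blob.centroid_uv
            half = max(4, int(np.sqrt(blob.area)))
            windows[m] = (int(cv_) - half, int(cu) - half, int(cv_) + half, int(cu) + half)
            if hists[m] is None:
                hists[m] = _hue_histogram(hsv, blob.pixels)
            last_uv[m] = blob.centroid_uv
            lost[m] = 0
            obs[m].append(MarkerObservation(frame=idx, marker=m, centroid_uv=blob.centroid_uv,
                                            centroid_mm=centroid3d, pixel_count=blob.area))
    return obs


def observations_to_trajectories(obs: dict[str, list[MarkerObservation | None]],
                                 times: np.ndarray) -> dict[str, FingertipTrajectory]:
    """Assemble per-marker observation sequences into trajectories,
    dropping gap frames."""
    out = {}
    for m, seq in obs.items():
        keep = [(times[o.frame] if o.frame < len(times) else None, o)
                for o in seq if o is not None]
        keep = [(t, o) for t, o in keep if t is not None]
        if not keep:
            continue
        t = np.array([k[0] for k in keep])
        xyz = np.vstack([k[1].centroid_mm for k in keep])
        out[m] = FingertipTrajectory(m, t, xyz)
    return out
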