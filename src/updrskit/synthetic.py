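"""Synthetic generator for UPDRS upper-limb task performances.

Produces ground-truth-known fingertip trajectories (and optionally rendered
RGB-D frames) emulating finger tapping (FT), hand opening-closing (OC) and
pronation-supination (PS) across severity levels, so that every downstream
stage — tracking, metrics, kinematics, selection, classification — is
testable without capture hardware.

The scalar movement profile is a raised cosine per cycle (aperture is never
negative), with severity expressed through the axes clinicians rate:
amplitude, speed/frequency, cycle-to-cycle variability, amplitude decrement,
and hesitations (flat holds inserted at cycle minima, where halts occur
clinically).  This keeps the per-cycle amplitude/period/speed ground truth
exact and in closed form: cycle *i* has amplitude
``A_i = A0 * (1 - decrement_rate)**i * (1 + eps_i)`` with
``eps_i ~ N(0, amplitude_cv)``, period ``T_i = T0 * (1 + eta_i)`` with
``eta_i ~ N(0, period_cv)``, and phase peak speed ``pi * A_i / T_i``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .camera import CameraModel
from .trajectories import FINGERS, PALM, FingertipTrajectory, TaskKind, TaskRecording

__all__ = [
    "MotionParams",
    "ScalarProfile",
    "HandRig",
    "SeverityPreset",
    "MARKER_COLORS",
    "RGBDFrame",
    "generate_scalar_profile",
    "embed_in_3d",
    "generate_cohort",
    "load_default_presets",
    "render_frames",
]


@dataclass(frozen=True)
class MotionParams:
    """Parameters of one synthetic task performance.

    ``base_amplitude`` is the cycle excursion: mm of aperture for FT/OC,
    degrees of rotation for PS.  ``baseline`` is the aperture at full
    closure (marker centres never quite coincide on a real hand); the
    profile oscillates between ``baseline`` and ``baseline + A_i``.
    """

    task: TaskKind = TaskKind.FT
    base_amplitude: float = 60.0       # mm (FT/OC) or degrees (PS)
    base_frequency: float = 2.0        # Hz
    n_cycles: int = 10
    amplitude_cv: float = 0.0
    period_cv: float = 0.0
    decrement_rate: float = 0.0        # fractional amplitude loss per cycle
    hesitation_prob: float = 0.0       # probability of a hold per cycle
    hesitation_duration: float = 0.3   # s
    noise_sd: float = 0.0              # mm (or degrees) of additive noise
    sample_rate: float = 60.0          # Hz
    baseline: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        vals = [self.base_amplitude, self.base_frequency, self.amplitude_cv,
                self.period_cv, self.decrement_rate, self.hesitation_prob,
                self.hesitation_duration, self.noise_sd, self.sample_rate,
                self.baseline]
        if not all(np.isfinite(vals)):
            raise ValueError("motion parameters must be finite")
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.amplitude_cv < 0 or self.period_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if not 0 <= self.decrement_rate < 1:
            raise ValueError("decrement_rate must be in [0, 1)")
        if not 0 <= self.hesitation_prob <= 1:
            raise ValueError("hesitation_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.base_amplitude <= 0:
            raise ValueError("noise_sd must be >= 0 and base_amplitude > 0")
        # at least 4 samples per half-phase so cycles are resolvable
        if self.sample_rate < 8 * self.base_frequency:
            raise ValueError("sample_rate must be >= 8 * base_frequency")
        object.__setattr__(self, "task", TaskKind.coerce(self.task))


@dataclass
class ScalarProfile:
    """A sampled aperture-or-angle profile plus its exact per-cycle table."""

    t: np.ndarray
    value: np.ndarray
    rate: float
    cycles: pd.DataFrame
    params: MotionParams


def generate_scalar_profile(params: MotionParams,
                            rng: np.random.Generator | None = None) -> ScalarProfile:
    """Generate the quasi-periodic scalar task signal for one performance.

    Returns the sampled signal together with the ground-truth per-cycle
    table (amplitude, period, hold, duration, per-phase peak speeds).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_cycles
    idx = np.arange(n)

    eps = rng.normal(0.0, params.amplitude_cv, size=n) if params.amplitude_cv else np.zeros(n)
    eta = rng.normal(0.0, params.period_cv, size=n) if params.period_cv else np.zeros(n)
    amp = params.base_amplitude * (1.0 - params.decrement_rate) ** idx * np.clip(1.0 + eps, 0.05, None)
    T0 = 1.0 / params.base_frequency
    period = T0 * np.clip(1.0 + eta, 0.2, None)
    hes = rng.random(n) < params.hesitation_prob if params.hesitation_prob else np.zeros(n, bool)
    hold = np.where(hes, params.hesitation_duration, 0.0)

    # each cycle = [hold at the minimum][raised-cosine beat of length T_i]
    cycle_len = hold + period
    starts = np.concatenate([[0.0], np.cumsum(cycle_len)])
    total = starts[-1]

    dt = 1.0 / params.sample_rate
    t = np.arange(0.0, total + 0.5 * dt, dt)   # endpoint included: ends at a minimum
    # locate each sample's cycle and phase within it
    ci = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n - 1)
    tau = t - starts[ci] - hold[ci]          # time since the beat started
    in_beat = tau >= 0
    value = np.full(t.shape, float(params.baseline))
    value[in_beat] += amp[ci[in_beat]] * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * tau[in_beat] / period[ci[in_beat]]))
    if params.noise_sd:
        value = value + rng.normal(0.0, params.noise_sd, size=value.shape)

    cycles = pd.DataFrame({
        "cycle": idx,
        "t_start": starts[:-1],
        "hold_s": hold,
        "period_s": period,
        "duration_s": cycle_len,
        "amplitude": amp,
        "max_opening": params.baseline + amp,
        "max_speed_opening": np.pi * amp / period,
        "max_speed_closing": np.pi * amp / period,
    })
    return ScalarProfile(t=t, value=value, rate=params.sample_rate, cycles=cycles, params=params)


# ---------------------------------------------------------------------------
# hand rig and 3D embedding
# ---------------------------------------------------------------------------

_DEFAULT_OFFSETS = {
    "thumb": (-45.0, -15.0, -10.0),
    "index": (-18.0, 60.0, -5.0),
    "middle": (0.0, 68.0, 0.0),
    "ring": (18.0, 62.0, 0.0),
    "pinky": (38.0, 48.0, 5.0),
}


@dataclass
class HandRig:
    """Static geometry of the gloved hand: palm centre plus finger offsets (mm)."""

    palm_center: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 400.0]))
    offsets: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: np.array(v) for k, v in _DEFAULT_OFFSETS.items()})
    marker_radius_px: int = 6
    palm_marker_radius_px: int = 11

    def __post_init__(self):
        self.palm_center = np.asarray(self.palm_center, dtype=float)
        self.offsets = {k: np.asarray(v, dtype=float) for k, v in self.offsets.items()}
        vecs = list(self.offsets.values())
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                if np.allclose(vecs[i], vecs[j]):
                    raise ValueError("finger offsets must be distinct")
        if np.linalg.norm(self.offsets["pinky"]) <= 0:
            raise ValueError("pinky-palm distance must be positive")


def _rot_y(deg: np.ndarray) -> np.ndarray:
    """Stack of rotation matrices about the vertical (Y) axis, degrees."""
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    R = np.zeros((a.size, 3, 3))
    R[:, 0, 0] = c
    R[:, 0, 2] = s
    R[:, 1, 1] = 1.0
    R[:, 2, 0] = -s
    R[:, 2, 2] = c
    return R


def embed_in_3d(profile: ScalarProfile, rig: HandRig | None = None,
                task: TaskKind | str | None = None) -> TaskRecording:
    """Turn a scalar profile into 3D fingertip trajectories for its task.

    FT: the index tip moves along the fixed thumb->index direction so that
    ||index - thumb|| equals the profile.  OC: the four finger tips scale
    radially from the palm so their mean tip-palm distance equals the
    profile.  PS: the whole rig rotates about the vertical axis through the
    palm by the profile angle.  The task-signal extraction in
    :mod:`updrskit.kinematics` inverts each mapping.
    """
    rig = rig or HandRig()
    task = TaskKind.coerce(task or profile.params.task)
    if not np.all(np.isfinite(profile.value)):
        raise ValueError("profile contains non-finite values")
    t = profile.t
    n = t.size
    pos = {f: np.tile(rig.palm_center + rig.offsets[f], (n, 1)) for f in FINGERS}
    pos[PALM] = np.tile(rig.palm_center, (n, 1))

    if task is TaskKind.FT:
        u = rig.offsets["index"] - rig.offsets["thumb"]
        u = u / np.linalg.norm(u)
        pos["index"] = pos["thumb"] + u[None, :] * profile.value[:, None]
    elif task is TaskKind.OC:
        four = ("index", "middle", "ring", "pinky")
        mean_d = np.mean([np.linalg.norm(rig.offsets[f]) for f in four])
        scale = profile.value / mean_d
        for f in four:
            pos[f] = pos[PALM] + rig.offsets[f][None, :] * scale[:, None]
    elif task is TaskKind.PS:
        # zero the pinky's rest azimuth first, so the rotation profile IS the
        # azimuth of the pinky-palm vector in the horizontal plane and the
        # angle extraction inverts the embedding exactly
        az0 = np.degrees(np.arctan2(rig.offsets["pinky"][0], rig.offsets["pinky"][2]))
        R = _rot_y(profile.value - az0)
        for f in FINGERS:
            pos[f] = pos[PALM] + np.einsum("nij,j->ni", R, rig.offsets[f])
    else:  # pragma: no cover - TaskKind.coerce already rejects
        raise ValueError(f"unknown task: {task}")

    trajs = {f: FingertipTrajectory(f, t, p) for f, p in pos.items()}
    return TaskRecording(task=task, trajectories=trajs, ground_truth=profile.cycles,
                         meta={"profile_rate": profile.rate, "params": profile.params})


# ---------------------------------------------------------------------------
# severity presets and cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SeverityPreset:
    """Per-severity-class parameter ranges for one task.

    ``classes`` maps "HC" and the UPDRS classes 0-3 to ``{field: (lo, hi)}``
    ranges from which :func:`generate_cohort` draws uniformly.  The shipped
    defaults make class-wise mean amplitude and frequency strictly decrease
    and variability, decrement and hesitation rate strictly increase with
    class, the ordering clinicians rate as worsening.
    """

    task: TaskKind
    classes: dict[str, dict[str, tuple[float, float]]]

    def __post_init__(self):
        self.task = TaskKind.coerce(self.task)
        if not self.classes:
            raise ValueError("preset has no classes")

    def class_names(self) -> list[str]:
        return list(self.classes)


def load_default_presets(task: TaskKind | str, variant: str = "clinical") -> SeverityPreset:
    """Load the packaged severity presets for a task.

    ``variant="clinical"`` is the realistic severity ladder (HC drawn like
    UPDRS 0 with tighter variance); ``variant="separated"`` (FT only) pulls
    the class ranges apart so they are separable by construction — the
    regime used to validate the classifier chain itself.
    """
    task = TaskKind.coerce(task)
    key = task.value if variant == "clinical" else f"{task.value}_SEPARATED"
    ref = importlib.resources.files("updrskit.data") / "severity_presets.yaml"
    raw = yaml.safe_load(ref.read_text())
    if key not in raw:
        raise ValueError(f"no preset {key!r} in the packaged preset file")
    classes = {str(k): {f: tuple(v) for f, v in spec.items()}
               for k, spec in raw[key].items()}
    return SeverityPreset(task=task, classes=classes)


def params_for_class(preset: SeverityPreset, cls: str,
                     rng: np.random.Generator, **overrides) -> MotionParams:
    """Draw one MotionParams uniformly from a preset class's ranges."""
    spec = preset.classes[str(cls)]
    draw = {f: float(rng.uniform(lo, hi)) for f, (lo, hi) in spec.items()}
    n_cycles = int(round(draw.pop("n_cycles", 15)))
    draw.update(overrides)
    return MotionParams(task=preset.task, n_cycles=n_cycles, **draw)


def generate_cohort(presets: SeverityPreset, n_per_class: int, seed: int,
                    rig: HandRig | None = None, **overrides) -> list[TaskRecording]:
    """Generate a labelled cohort of recordings, ``n_per_class`` per severity class.

    A pure function of (presets, n_per_class, seed): repeated calls produce
    identical trajectories.  "HC" rows get ``cohort="HC"`` and no label;
    numeric classes get ``cohort="PD"`` and the class as label.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    recordings = []
    for cls in presets.class_names():
        for _ in range(n_per_class):
            params = params_for_class(presets, cls, rng, **overrides)
            profile = generate_scalar_profile(params, rng)
            rec = embed_in_3d(profile, rig, presets.task)
            if str(cls).upper() == "HC":
                rec.cohort, rec.label = "HC", None
            else:
                rec.cohort, rec.label = "PD", int(cls)
            recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# RGB-D frame rendering (fixture for the marker tracker)
# ---------------------------------------------------------------------------

#: Marker hue (degrees) and render RGB per finger; hues are spaced to keep the
#: HSV threshold triplets trivially separable and away from the hue wrap.
MARKER_COLORS = {
    "thumb": 30.0,
    "index": 100.0,
    "middle": 170.0,
    "ring": 240.0,
    "pinky": 310.0,
}


def _hue_to_rgb(hue_deg: float) -> np.ndarray:
    import colorsys
    r, g, b = colorsys.hsv_to_rgb(hue_deg / 360.0, 1.0, 1.0)
    return np.array([r, g, b]) * 255.0


@dataclass
class RGBDFrame:
    index: int
    rgb: np.ndarray      # (h, w, 3) uint8
    depth: np.ndarray    # (h, w) uint16, mm


def render_frames(recording: TaskRecording, rig: HandRig | None = None,
                  camera: CameraModel | None = None, stride: int = 1):
    """Render a recording as synthetic RGB-D frames (generator).

    Each fingertip becomes a filled coloured disc at its pinhole projection
    with true depth (mm) at its pixels; the palm carries a white disc; a dark
    "glove" disc behind them makes depth-based hand segmentation meaningful.
    Frames where any marker projects outside the image are skipped with a
    warning entry in ``recording.meta['skipped_frames']``.
    """
    from skimage.draw import disk

    rig = rig or HandRig()
    camera = camera or CameraModel(fx=600.0, fy=600.0, cx=320.0, cy=240.0,
                                   width=640, height=480)
    h, w = camera.height, camera.width
    skipped = recording.meta.setdefault("skipped_frames", [])
    n = len(recording[PALM])
    for i in range(0, n, stride):
        pts = {f: recording[f].xyz[i] for f in FINGERS}
        palm = recording[PALM].xyz[i]
        uv = {f: camera.project(p)[0] for f, p in pts.items()}
        uv_palm = camera.project(palm)[0]
        margin = rig.marker_radius_px
        ok = all(margin <= u < w - margin and margin <= v < h - margin
                 for u, v in list(uv.values()) + [uv_palm])
        if not ok:
            skipped.append(i)
            continue
        rgb = np.zeros((h, w, 3), dtype=np.uint8)
        depth = np.zeros((h, w), dtype=np.uint16)
        # glove: dark disc centred on the palm, large enough to cover the hand
        reach = max(np.hypot(*(uv[f] - uv_palm)) for f in FINGERS)
        rr, cc = disk((uv_palm[1], uv_palm[0]), reach + 3 * margin, shape=(h, w))
        rgb[rr, cc] = (35, 35, 35)
        depth[rr, cc] = np.uint16(round(palm[2]))
        # white palm marker
        rr, cc = disk((uv_palm[1], uv_palm[0]), rig.palm_marker_radius_px, shape=(h, w))
        rgb[rr, cc] = (255, 255, 255)
        depth[rr, cc] = np.uint16(round(palm[2]))
        # coloured fingertip markers
        for f in FINGERS:
            rr, cc = disk((uv[f][1], uv[f][0]), rig.marker_radius_px, shape=(h, w))
            rgb[rr, cc] = np.uint8(_hue_to_rgb(MARKER_COLORS[f]))
            depth[rr, cc] = np.uint16(round(pts[f][2]))
        yield RGBDFrame(index=i, rgb=rgb, depth=depth)
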