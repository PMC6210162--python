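"""Scalar task signals, movement-cycle segmentation and kinematic features.

Each task recording is reduced to a single scalar signal — thumb-index
distance (FT), fingers-to-palm aperture (OC), or unwrapped hand rotation
angle (PS) — which is segmented into movement cycles (minimum -> maximum ->
minimum).  Per-cycle quantities (maximum opening, amplitude, per-phase peak
speeds, durations) are summarised as the task feature vector: a mean (``*m``)
and a coefficient of variation (``*v``, CV = sigma/mu, sample std) per
quantity, plus the principal frequency of voluntary movement.

Feature naming follows the clinical convention: MO = maximum opening,
MA = movement amplitude (max-min excursion), MOS/MCS = maximum speed in the
opening/closing phase, MR = movement rotation, MSS/MPS = maximum speed in
the supination/pronation phase, D = movement (or phase) duration,
Freq = principal frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import detrend, find_peaks, periodogram, savgol_filter

from .trajectories import TaskKind, TaskRecording

__all__ = [
    "TaskSignal",
    "InsufficientCyclesError",
    "FEATURES",
    "NEGATIVE_CORRELATION_FEATURES",
    "extract_task_signal",
    "segment_cycles",
    "principal_frequency",
    "compute_features",
    "features_for_recording",
    "cohort_feature_matrix",
]

#: Feature vector composition per task.
FEATURES: dict[TaskKind, list[str]] = {
    TaskKind.FT: ["MOm", "MOv", "MOSm", "MOSv", "MCSm", "MCSv", "MAm", "MAv", "Freq", "Dv"],
    TaskKind.OC: ["MOSm", "MOSv", "MCSm", "MCSv", "MAm", "MAv", "Dv"],
    TaskKind.PS: ["MRm", "MRv", "MSSm", "MSSv", "MPSm", "MPSv", "Freq", "DSv", "DPv"],
}

#: Features that correlate negatively with severity (means and frequency:
#: amplitude, speed and rate fall as impairment worsens).  Their reciprocal
#: is used when a "larger = worse" orientation is needed for reporting.
NEGATIVE_CORRELATION_FEATURES = frozenset(
    {"MOm", "MOSm", "MCSm", "MAm", "Freq", "MRm", "MSSm", "MPSm"})


class InsufficientCyclesError(ValueError):
    """Raised when fewer than two movement cycles can be segmented."""


@dataclass
class TaskSignal:
    """Uniform-rate scalar task signal: mm (FT/OC aperture) or degrees (PS)."""

    values: np.ndarray
    rate: float
    task: TaskKind
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.task = TaskKind.coerce(self.task)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("task signal contains non-finite values")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.rate


def _gap_fraction(t: np.ndarray) -> float:
    """Fraction of the time base lost to sampling gaps (dt > 1.5 x median)."""
    if t.size < 3:
        return 0.0
    dt = np.diff(t)
    med = np.median(dt)
    gaps = dt[dt > 1.5 * med] - med
    return float(np.sum(gaps) / (t[-1] - t[0]))


def _resample_on_grid(traj, grid: np.ndarray) -> np.ndarray:
    return CubicSpline(traj.t, traj.xyz, axis=0)(grid)


def extract_task_signal(recording: TaskRecording, rate: float = 100.0,
                        oc_mode: str = "aperture",
                        max_gap_fraction: float = 0.2) -> TaskSignal:
    """Reduce a recording to its scalar task signal at a uniform rate.

    FT: ||index - thumb||.  OC: mean fingertip-to-palm distance over the
    four fingers (``oc_mode="index_y"`` instead takes the index-tip height
    relative to the palm).  PS: unwrapped angle of the pinky-palm vector
    projected on the horizontal X-Z plane, in degrees (defined up to the
    rig-dependent constant azimuth of the pinky).
    """
    task = recording.task
    needed = {TaskKind.FT: ["thumb", "index"],
              TaskKind.OC: ["index", "middle", "ring", "pinky", "palm"],
              TaskKind.PS: ["pinky", "palm"]}[task]
    if oc_mode == "index_y" and task is TaskKind.OC:
        needed = ["index", "palm"]
    trajs = {f: recording[f] for f in needed}
    for f, tr in trajs.items():
        gf = _gap_fraction(tr.t)
        if gf > max_gap_fraction:
            raise ValueError(f"finger {f!r} has {gf:.0%} of the recording lost to "
                             f"tracking gaps (limit {max_gap_fraction:.0%})")
    t0 = max(tr.t[0] for tr in trajs.values())
    t1 = min(tr.t[-1] for tr in trajs.values())
    if t1 <= t0:
        raise ValueError("finger trajectories have no overlapping time window")
    grid = t0 + np.arange(int(np.floor((t1 - t0) * rate)) + 1) / rate
    xyz = {f: _resample_on_grid(tr, grid) for f, tr in trajs.items()}

    if task is TaskKind.FT:
        values = np.linalg.norm(xyz["index"] - xyz["thumb"], axis=1)
    elif task is TaskKind.OC:
        if oc_mode == "index_y":
            values = xyz["index"][:, 1] - xyz["palm"][:, 1]
        elif oc_mode == "aperture":
            values = np.mean([np.linalg.norm(xyz[f] - xyz["palm"], axis=1)
                              for f in ("index", "middle", "ring", "pinky")], axis=0)
        else:
            raise ValueError(f"unknown oc_mode: {oc_mode!r}")
    else:  # PS
        rel = xyz["pinky"] - xyz["palm"]
        values = np.degrees(np.unwrap(np.arctan2(rel[:, 0], rel[:, 2])))
    return TaskSignal(values=values, rate=rate, task=task, t0=grid[0])


def principal_frequency(signal: TaskSignal, band: tuple[float, float] = (0.25, 8.0),
                        resolution: float = 0.05,
                        min_peak_snr: float = 50.0) -> float | None:
    """Dominant voluntary-movement frequency (Hz) of the detrended signal.

    Periodogram zero-padded to at least ``resolution`` Hz bin spacing,
    restricted to ``band``.  The peak is accepted only when it rises at
    least ``min_peak_snr`` times above the median band power — a
    quasi-periodic movement concentrates orders of magnitude more power at
    its rate than any single noise bin, while pure noise (no voluntary
    movement, peak/median below ~20 empirically) returns None.
    """
    x = signal.values
    if signal.duration < 3.0:
        raise ValueError("principal frequency needs at least 3 s of signal")
    nfft = int(2 ** np.ceil(np.log2(max(x.size, signal.rate / resolution))))
    f, p = periodogram(detrend(x), fs=signal.rate, nfft=nfft)
    m = (f >= band[0]) & (f <= band[1])
    f, p = f[m], p[m]
    if not p.size or p.max() <= 0:
        return None
    med = np.median(p)
    if med > 0 and p.max() / med < min_peak_snr:
        return None
    return float(f[np.argmax(p)])


def _smooth_window(rate: float, period: float) -> int:
    """Odd smoothing-window length ~ 1/4 of the movement period, >= 5 samples."""
    w = int(round(rate * period / 4.0))
    w = max(w, 5)
    return w + 1 if w % 2 == 0 else w


def segment_cycles(signal: TaskSignal, prominence_frac: float = 0.2,
                   smooth_window: int | None = None) -> pd.DataFrame:
    """Segment the task signal into movement cycles (minimum -> minimum).

    The signal is smoothed with a Savitzky-Golay (polynomial) filter whose
    window is about a quarter of the movement period; extrema are detected
    with prominence at least ``prominence_frac`` of the interquartile range.
    The opening phase runs minimum -> maximum (supination for PS), the
    closing phase maximum -> minimum.  Per-phase peak speeds are the maxima
    of |ds/dt| computed by central differences on the smoothed signal.
    """
    if signal.duration < 2.0:
        raise InsufficientCyclesError("need at least 2 s of signal to segment cycles")
    x = signal.values
    rate = signal.rate
    if smooth_window is None:
        try:
            f0 = principal_frequency(signal)
        except ValueError:
            f0 = None
        if f0 is None:
            raise InsufficientCyclesError("insufficient cycles: no dominant movement frequency")
        smooth_window = _smooth_window(rate, 1.0 / f0)
    smooth_window = min(smooth_window, x.size - 1 if (x.size - 1) % 2 else x.size - 2)
    s = savgol_filter(x, smooth_window, polyorder=3)
    # peak speeds are maxima of a noisy derivative and bias upward; a second,
    # slightly shorter polynomial smoothing pass on the derivative suppresses
    # that bias without attenuating the true peak appreciably
    w2 = max(5, int(round(0.7 * smooth_window)))
    w2 += 1 - w2 % 2
    v = savgol_filter(np.gradient(s, 1.0 / rate), min(w2, smooth_window), polyorder=3)

    iqr = np.subtract(*np.percentile(s, [75, 25]))
    prom = prominence_frac * iqr
    if prom <= 0:
        raise InsufficientCyclesError("insufficient cycles: flat signal")
    maxima, _ = find_peaks(s, prominence=prom)
    minima, _ = find_peaks(-s, prominence=prom)
    # treat the signal ends as cycle boundaries when the first/last extremum
    # detected is a maximum (profiles start and end at a minimum)
    if maxima.size and (not minima.size or maxima[0] < minima[0]):
        minima = np.concatenate([[int(np.argmin(s[:maxima[0]]))], minima])
    if maxima.size and maxima[-1] > (minima[-1] if minima.size else -1):
        minima = np.concatenate([minima, [maxima[-1] + int(np.argmin(s[maxima[-1]:]))]])

    rows = []
    t = signal.t
    for a, b in zip(minima[:-1], minima[1:]):
        inside = maxima[(maxima > a) & (maxima < b)]
        if not inside.size:
            continue
        pk = inside[np.argmax(s[inside])]
        rows.append({
            "start": int(a), "peak": int(pk), "end": int(b),
            "t_start": float(t[a]),
            "duration_s": float(t[b] - t[a]),
            "open_duration_s": float(t[pk] - t[a]),
            "close_duration_s": float(t[b] - t[pk]),
            "max_opening": float(s[pk]),
            "amplitude": float(s[pk] - 0.5 * (s[a] + s[b])),
            "max_speed_opening": float(np.max(np.abs(v[a:pk + 1]))),
            "max_speed_closing": float(np.max(np.abs(v[pk:b + 1]))),
        })
    if len(rows) < 2:
        raise InsufficientCyclesError(f"insufficient cycles: found {len(rows)}, need >= 2")
    return pd.DataFrame(rows)


def _cv(x: np.ndarray, name: str) -> float:
    mu = np.mean(x)
    if mu == 0:
        warnings.warn(f"CV of {name} undefined (zero mean); reported as NaN")
        return float("nan")
    return float(np.std(x, ddof=1) / mu)


def compute_features(cycles: pd.DataFrame, signal: TaskSignal | None = None,
                     task: TaskKind | None = None) -> pd.Series:
    """Summarise a cycle table as the task's named kinematic feature vector.

    ``*m`` features are means over cycles, ``*v`` features coefficients of
    variation (sample std / mean).  ``Freq`` (FT and PS) is the principal
    frequency of the signal and requires ``signal``.
    """
    if len(cycles) < 2:
        raise InsufficientCyclesError("feature computation needs at least 2 cycles")
    task = TaskKind.coerce(task or (signal.task if signal is not None else TaskKind.FT))
    amp = cycles["amplitude"].to_numpy()
    mo = cycles["max_opening"].to_numpy()
    vo = cycles["max_speed_opening"].to_numpy()
    vc = cycles["max_speed_closing"].to_numpy()
    dur = cycles["duration_s"].to_numpy()

    out: dict[str, float] = {}
    if task is TaskKind.FT:
        out.update(MOm=float(mo.mean()), MOv=_cv(mo, "max opening"),
                   MOSm=float(vo.mean()), MOSv=_cv(vo, "opening speed"),
                   MCSm=float(vc.mean()), MCSv=_cv(vc, "closing speed"),
                   MAm=float(amp.mean()), MAv=_cv(amp, "amplitude"),
                   Dv=_cv(dur, "duration"))
    elif task is TaskKind.OC:
        out.update(MOSm=float(vo.mean()), MOSv=_cv(vo, "opening speed"),
                   MCSm=float(vc.mean()), MCSv=_cv(vc, "closing speed"),
                   MAm=float(amp.mean()), MAv=_cv(amp, "amplitude"),
                   Dv=_cv(dur, "duration"))
    else:  # PS: opening phase = supination, closing = pronation
        out.update(MRm=float(amp.mean()), MRv=_cv(amp, "rotation"),
                   MSSm=float(vo.mean()), MSSv=_cv(vo, "supination speed"),
                   MPSm=float(vc.mean()), MPSv=_cv(vc, "pronation speed"),
                   DSv=_cv(cycles["open_duration_s"].to_numpy(), "supination duration"),
                   DPv=_cv(cycles["close_duration_s"].to_numpy(), "pronation duration"))
    if "Freq" in FEATURES[task]:
        if signal is None:
            raise ValueError("Freq requires the task signal")
        f = principal_frequency(signal)
        out["Freq"] = float("nan") if f is None else f
    return pd.Series(out, dtype=float).reindex(FEATURES[task])


def features_for_recording(recording: TaskRecording, rate: float = 100.0,
                           oc_mode: str = "aperture") -> pd.Series:
    """Full chain: task signal -> cycle table -> feature vector."""
    sig = extract_task_signal(recording, rate=rate, oc_mode=oc_mode)
    cycles = segment_cycles(sig)
    return compute_features(cycles, sig)


def cohort_feature_matrix(recordings, rate: float = 100.0) -> pd.DataFrame:
    """Feature matrix for a cohort; adds ``score`` (UPDRS class, NaN for HC)
    and ``cohort`` columns alongside the kinematic features."""
    rows = []
    for i, rec in enumerate(recordings):
        feats = features_for_recording(rec, rate=rate)
        feats["score"] = np.nan if rec.label is None else rec.label
        feats["cohort"] = rec.cohort or ("PD" if rec.label is not None else "HC")
        rows.append(feats.rename(i))
    return pd.DataFrame(rows)
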