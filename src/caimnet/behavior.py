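"""Treadmill kinematics: linear velocity from two optical sensors and
rest/run bout segmentation with a fuzzy-logic threshold.

A head-fixed mouse runs on a spherical treadmill read out by two surface
sensors mounted at the ball's equator, an angle ``theta`` apart.  The two
vertical sensor readings are decomposed into perpendicular velocity
components and combined into a linear speed, which is then segmented into
sustained "running" and "resting" bouts via a sigmoidal membership
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

FS = 20.0  # Hz, common sampling rate of speed and fluorescence

REST, RUN, UNCLASSIFIED = "rest", "run", "unclassified"


@dataclass
class SpeedTrace:
    """Linear speed (cm/s) uniformly sampled at ``fs`` Hz."""

    t: np.ndarray
    v: np.ndarray
    fs: float = FS

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have the same shape")

    @property
    def n_samples(self) -> int:
        return self.v.size


@dataclass
class BoutSegmentation:
    """Disjoint, ordered, half-open ``[start, end)`` sample intervals."""

    intervals: list[tuple[int, int, str]]
    n_samples: int
    fs: float = FS
    params: dict = field(default_factory=dict)

    def mask(self, label: str) -> np.ndarray:
        out = np.zeros(self.n_samples, dtype=bool)
        for s, e, lab in self.intervals:
            if lab == label:
                out[s:e] = True
        return out

    def bouts(self, label: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def state_time_s(self, label: str) -> float:
        return sum(e - s for s, e, lab in self.intervals if lab == label) / self.fs


@dataclass
class SessionQC:
    time_in_rest_s: float
    time_in_run_s: float
    n_run_bouts: int
    eligible_for_locomotion_analysis: bool


def compute_velocity(
    L: np.ndarray,
    R: np.ndarray,
    theta: float,
    t: np.ndarray | None = None,
    fs_out: float = FS,
) -> SpeedTrace:
    """Linear speed from the two sensor readings.

    The perpendicular components are ``X = (L - R cos(theta)) / sin(theta)``
    and ``Y = R``; speed is ``V = sqrt(X^2 + Y^2)``, linearly interpolated
    onto a uniform ``fs_out`` grid when the input has its own time base.
    """
    L = np.asarray(L, dtype=float)
    R = np.asarray(R, dtype=float)
    if L.shape != R.shape:
        raise ValueError("L and R must have the same length")
    s = np.sin(theta)
    if abs(s) < 1e-12:
        raise ValueError("theta must lie strictly between 0 and pi (sin(theta) != 0)")
    X = (L - R * np.cos(theta)) / s
    Y = R
    V = np.hypot(X, Y)
    if t is None:
        t_out = np.arange(V.size) / fs_out
        return SpeedTrace(t_out, V, fs=fs_out)
    t = np.asarray(t, dtype=float)
    t_out = np.arange(t[0], t[-1] + 0.5 / fs_out, 1.0 / fs_out)
    v_out = np.interp(t_out, t, V)
    return SpeedTrace(t_out - t_out[0], v_out, fs=fs_out)


def fuzzy_membership(v: np.ndarray, a: float, c: float) -> np.ndarray:
    """Sigmoidal membership ``F(V) = 1 / (1 + exp(-a (V - c)))``."""
    if a <= 0:
        raise ValueError("a must be positive")
    return 1.0 / (1.0 + np.exp(-a * (np.asarray(v, dtype=float) - c)))


def segment_bouts(
    speed: SpeedTrace,
    a: float = 0.8,
    smooth_s: float = 1.5,
    frac_thresh: float = 0.10,
    min_s: float = 2.0,
    c_floor: float = 5.0,
    c_percentile: float = 20.0,
) -> BoutSegmentation:
    """Segment a speed trace into rest / run / unclassified intervals.

    The velocity threshold ``c`` is the session's ``c_percentile``-th
    percentile of speed or ``c_floor`` cm/s, whichever is higher.  Each
    sample's fuzzy membership is smoothed with a ``smooth_s`` moving
    average and thresholded at ``frac_thresh`` of the smoothed trace's
    per-session maximum; supra-threshold stretches at least ``min_s`` long
    become run bouts, sub-threshold stretches at least ``min_s`` long
    become rest bouts, and everything else is unclassified.
    """
    v = speed.v
    if v.size == 0:
        raise ValueError("empty speed trace")
    fs = speed.fs
    c = max(float(np.percentile(v, c_percentile)), c_floor)
    m = fuzzy_membership(v, a, c)
    w = max(int(round(smooth_s * fs)), 1)
    m_smooth = uniform_filter1d(m, size=w, mode="nearest")
    peak = float(m_smooth.max())
    # A session whose smoothed membership never reaches the sigmoid midpoint
    # contains no sample above the velocity threshold c: all rest.
    if peak < 0.5:
        supra = np.zeros(v.size, dtype=bool)
    else:
        supra = m_smooth >= frac_thresh * peak  # ties count as supra-threshold
    min_n = int(np.ceil(min_s * fs))
    intervals: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, v.size + 1):
        if i == v.size or supra[i] != supra[start]:
            length = i - start
            if length >= min_n:
                label = RUN if supra[start] else REST
            else:
                label = UNCLASSIFIED
            intervals.append((start, i, label))
            start = i
    params = dict(a=a, c=c, smooth_s=smooth_s, frac_thresh=frac_thresh, min_s=min_s)
    return BoutSegmentation(intervals, n_samples=v.size, fs=fs, params=params)


def session_qc(
    seg: BoutSegmentation,
    min_state_time_s: float = 60.0,
    min_run_bouts: int = 5,
) -> SessionQC:
    """Session eligibility for locomotion-conditioned analysis.

    A session qualifies when at least ``min_state_time_s`` was spent in each
    behavioral state and it contains at least ``min_run_bouts`` run bouts.
    """
    t_rest = seg.state_time_s(REST)
    t_run = seg.state_time_s(RUN)
    n_run = len(seg.bouts(RUN))
    eligible = min(t_rest, t_run) >= min_state_time_s and n_run >= min_run_bouts
    return SessionQC(t_rest, t_run, n_run, eligible)


def bout_kinematics(speed: SpeedTrace, seg: BoutSegmentation) -> dict:
    """Run-bout summary: count, mean duration, mean bout speed, session speed.

    Mean bout speed averages the per-bout mean speeds so long bouts do not
    dominate; session mean speed averages the full trace.
    """
    run_bouts = seg.bouts(RUN)
    durations = [(e - s) / seg.fs for s, e in run_bouts]
    bout_speeds = [float(speed.v[s:e].mean()) for s, e in run_bouts]
    return {
        "n_bouts": len(run_bouts),
        "mean_bout_duration_s": float(np.mean(durations)) if durations else 0.0,
        "mean_bout_speed": float(np.mean(bout_speeds)) if bout_speeds else 0.0,
        "session_mean_speed": float(speed.v.mean()),
    }
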