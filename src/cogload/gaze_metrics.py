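"""Gaze-based workload metrics: I-VT fixation classification, fixation/saccade
rates, the Nearest Neighbor Index of fixation dispersion, and saccadic
intrusion detection.

Under higher cognitive load, visual scanning becomes less repetitive: fixation
points spread out (NNI rises toward and past 1), and small involuntary
horizontal "out-and-back" movements (saccadic intrusions, SIs) become faster.
The I-VT filter classifies each gaze sample as saccade (angular velocity at or
above a threshold, default 30 deg/s) or fixation; consecutive fixation samples
merge into fixations whose centroids feed the NNI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from cogload.errors import DegenerateInputError
from cogload.signal_io import TimeSeries

__all__ = [
    "Fixation",
    "FixationSet",
    "Saccade",
    "SIEvent",
    "NNIResult",
    "ivt_classify",
    "fixation_rate",
    "saccade_rate",
    "nni",
    "detect_si",
    "median_si_velocity",
]

#: default I-VT velocity threshold, deg/s
IVT_THRESHOLD = 30.0
#: fixations shorter than this are discarded, s
MIN_FIXATION_S = 0.06
#: SI definition: return tolerance (deg) and admissible out-and-back window (s)
SI_RETURN_TOL = 0.4
SI_WINDOW = (0.06, 0.87)
#: minimum excursion amplitude to consider, deg
SI_MIN_AMPLITUDE = 0.1
#: excursions beyond this are ordinary saccades, not intrusions, deg
SI_MAX_AMPLITUDE = 2.5
#: baseline = median of this much preceding signal, s
SI_BASELINE_S = 0.1


@dataclass
class Fixation:
    start: float
    end: float
    fx: float
    fy: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Saccade:
    start: float
    end: float


@dataclass
class FixationSet:
    """Classified fixations plus the bounding-rectangle area of the gaze field."""

    fixations: list[Fixation]
    area: float  # deg^2, bounding rectangle of the gaze coordinates

    @property
    def n(self) -> int:
        return len(self.fixations)

    def centroids(self) -> np.ndarray:
        return np.array([[f.fx, f.fy] for f in self.fixations]).reshape(-1, 2)

    def total_duration(self) -> float:
        return float(sum(f.duration for f in self.fixations))


@dataclass
class SIEvent:
    """One saccadic intrusion: out-and-back horizontal excursion."""

    onset: float
    ret: float
    amplitude: float  # deg, peak excursion from the pre-event baseline
    velocity: float  # deg/s, out-and-back path / elapsed time = 2*amp/duration


@dataclass
class NNIResult:
    d_nn: float
    d_mrd: float
    nni: float


def _angular_velocity(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample gaze speed (deg/s) by central difference, one-sided at ends."""
    n = len(t)
    v = np.zeros(n)
    if n < 2:
        return v
    dx = np.gradient(x, t)
    dy = np.gradient(y, t)
    v = np.hypot(dx, dy)
    return v


def ivt_classify(
    gaze: TimeSeries,
    velocity_threshold: float = IVT_THRESHOLD,
    min_fixation_s: float = MIN_FIXATION_S,
) -> tuple[FixationSet, list[Saccade]]:
    """Velocity-threshold (I-VT) classification of gaze samples.

    Samples with angular velocity >= ``velocity_threshold`` are saccades, the
    rest fixations. Consecutive fixation samples merge; invalid samples break
    runs. Fixations shorter than ``min_fixation_s`` are discarded. The
    fixation centroid is the mean of its member samples.
    """
    x = gaze.channels["gaze_x_deg"]
    y = gaze.channels["gaze_y_deg"]
    ok = gaze.valid("gaze_x_deg") & gaze.valid("gaze_y_deg")
    ok &= np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        warnings.warn("ivt_classify: all gaze samples invalid", stacklevel=2)
        return FixationSet([], 0.0), []
    t = gaze.t
    v = _angular_velocity(t, x, y)
    # states: 0 fixation, 1 saccade, -1 invalid
    state = np.where(v >= velocity_threshold, 1, 0)
    state[~ok] = -1

    area = float((x[ok].max() - x[ok].min()) * (y[ok].max() - y[ok].min()))

    fixations: list[Fixation] = []
    saccades: list[Saccade] = []
    i, n = 0, len(t)
    while i < n:
        s = state[i]
        j = i
        while j < n and state[j] == s:
            j += 1
        if s == 0:
            dur = t[j - 1] - t[i]
            if dur >= min_fixation_s:
                fixations.append(
                    Fixation(float(t[i]), float(t[j - 1]), float(x[i:j].mean()), float(y[i:j].mean()))
                )
        elif s == 1:
            saccades.append(Saccade(float(t[i]), float(t[j - 1])))
        i = j
    return FixationSet(fixations, area), saccades


def fixation_rate(fixations: FixationSet, duration: float) -> float:
    """Fraction of the epoch spent in fixations: sum of durations / duration."""
    if duration <= 0:
        raise DegenerateInputError("fixation_rate: duration must be positive")
    return fixations.total_duration() / duration


def saccade_rate(saccades: list[Saccade], duration: float) -> float:
    """Saccade count per second."""
    if duration <= 0:
        raise DegenerateInputError("saccade_rate: duration must be positive")
    return len(saccades) / duration


def nni(points: FixationSet | np.ndarray, area: float | None = None) -> NNIResult:
    """Nearest Neighbor Index of a planar point set (Clark-Evans, uncorrected).

    d_nn is the mean nearest-neighbour Euclidean distance; d_mrd the expected
    value 0.5*sqrt(area/N) under complete spatial randomness over the bounding
    rectangle of the points (or a caller-supplied ``area``). NNI = d_nn/d_mrd:
    about 1 for random, <1 clustered, >1 dispersed scanning.

    Raises
    ------
    DegenerateInputError : fewer than 2 points
    """
    pts = points.centroids() if isinstance(points, FixationSet) else np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DegenerateInputError("nni needs at least 2 points")
    n = pts.shape[0]
    if area is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        area = float(span[0] * span[1])
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    d_nn = float(dists[:, 1].mean())
    if area <= 0:
        warnings.warn("nni: degenerate (zero-area) point set; NNI set to 0", stacklevel=2)
        return NNIResult(d_nn=d_nn, d_mrd=0.0, nni=0.0)
    d_mrd = 0.5 * float(np.sqrt(area / n))
    return NNIResult(d_nn=d_nn, d_mrd=d_mrd, nni=d_nn / d_mrd)


def _walk_to_local_min(dev: np.ndarray, start: int, step: int) -> int:
    """Follow |deviation| downhill from ``start`` in direction ``step``."""
    i = start
    n = len(dev)
    while 0 <= i + step < n and dev[i + step] < dev[i]:
        i += step
    return i


def detect_si(
    horiz_gaze: TimeSeries,
    channel: str = "gaze_x_deg",
    min_amplitude: float = SI_MIN_AMPLITUDE,
    max_amplitude: float = SI_MAX_AMPLITUDE,
    return_tol: float = SI_RETURN_TOL,
    window: tuple[float, float] = SI_WINDOW,
    baseline_s: float = SI_BASELINE_S,
) -> list[SIEvent]:
    """Detect saccadic intrusions on the horizontal gaze channel.

    An SI is an excursion from a stable local baseline (median of the
    preceding ``baseline_s``) that leaves the ``return_tol`` neighbourhood
    and comes back to within ``return_tol`` of the baseline within ``window``
    seconds. Excursions larger than ``max_amplitude`` are ordinary saccades,
    not intrusions. A candidate that settles at a stable level away from the
    baseline is a gaze shift, not an out-and-back movement, and is abandoned
    immediately (so a saccade does not blind the detector for the whole
    870 ms window). Onset and return are refined to the local minima of
    |deviation| flanking the excursion, so the duration covers the full
    out-and-back path; the event velocity is that path over the elapsed
    time, 2*amplitude/duration.
    """
    t = horiz_gaze.t
    x = horiz_gaze.channels[channel]
    ok = horiz_gaze.valid(channel) & np.isfinite(x)
    n = len(t)
    if n == 0 or (t[-1] - t[0]) < window[1]:
        warnings.warn("detect_si: epoch shorter than the 870 ms SI window", stacklevel=2)
        return []
    fs = 1.0 / float(np.median(np.diff(t)))
    nbase = max(2, int(round(baseline_s * fs)))
    stable_tol = 2.0 * min_amplitude

    # sample k is "stable" when the trailing window is fully valid and its
    # peak-to-peak spread sits within the noise band
    def _stable_mask(width: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        if n >= width:
            win = np.lib.stride_tricks.sliding_window_view(x, width)
            ptp = win.max(axis=1) - win.min(axis=1)
            okwin = np.lib.stride_tricks.sliding_window_view(ok, width).all(axis=1)
            mask[width - 1 :] = (ptp <= stable_tol) & okwin
        return mask

    stable = _stable_mask(nbase)
    # abort uses a doubled window: the apex of a slow out-and-back pulse can
    # look flat for ~100 ms, but a real gaze shift stays flat much longer
    stable_long = _stable_mask(2 * nbase)

    events: list[SIEvent] = []
    i = nbase
    while i < n:
        if not (ok[i] and stable[i - 1]):
            i += 1
            continue
        baseline = float(np.median(x[i - nbase : i]))
        if abs(x[i] - baseline) <= min_amplitude:
            i += 1
            continue
        dev = np.abs(x - baseline)
        onset_cross = i
        # hysteresis: "left" only beyond return_tol + min_amplitude, so noise
        # cannot flicker a near-threshold gaze shift into an apparent return
        out_thresh = return_tol + min_amplitude
        left_out = False
        peak = dev[i]
        j = i
        ret_idx = -1
        while j < n and (t[j] - t[onset_cross]) <= window[1] + 0.1:
            if not ok[j]:
                break
            peak = max(peak, dev[j])
            if dev[j] > out_thresh:
                left_out = True
            elif left_out and dev[j] <= return_tol:
                ret_idx = j
                break
            if stable_long[j] and (t[j] - t[onset_cross]) > 2 * baseline_s:
                break  # settled at a new level: a gaze shift, not an SI
            j += 1
        if ret_idx < 0 or peak < min_amplitude or peak > max_amplitude:
            i = j + 1
            continue
        onset = _walk_to_local_min(dev, onset_cross, -1)
        ret = _walk_to_local_min(dev, ret_idx, +1)
        duration = float(t[ret] - t[onset])
        if window[0] <= duration <= window[1] and peak > 0:
            events.append(
                SIEvent(
                    onset=float(t[onset]),
                    ret=float(t[ret]),
                    amplitude=float(peak),
                    velocity=2.0 * float(peak) / duration,
                )
            )
        i = ret + 1 if ret > i else j + 1
    return events


def median_si_velocity(events: list[SIEvent]) -> float:
    """Median SI velocity in deg/s; NaN when there are no events."""
    if not events:
        return float("nan")
    return float(np.median([e.velocity for e in events]))
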