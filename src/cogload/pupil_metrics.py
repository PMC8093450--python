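"""Pupil-diameter workload metrics: L1NS, STDP, and the low-pass-filter metric.

Pupil diameter carries a task-evoked component: under higher cognitive load
the diameter fluctuates more in the 1-5 Hz range. The L1 Norm of Spectrum
(L1NS) sums the single-sided FFT amplitude components of the mean-subtracted
diameter between 1 and 5 Hz; restricting to >=1 Hz makes the index robust to
slow luminance drift. STDP is the sample standard deviation of the diameter,
and the LPF metric is the mean absolute value of the low-pass-filtered,
mean-subtracted diameter. All three are translation invariant and reported in
mm, per eye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from cogload.errors import DegenerateInputError, EpochRejectedError, ParameterError
from cogload.signal_io import TimeSeries, resample_uniform

__all__ = [
    "PupilEpoch",
    "PupilMetricResult",
    "epochs_from_gaze",
    "preprocess_pupil",
    "l1ns",
    "stdp",
    "lpf_metric",
    "compute_pupil_metrics",
]

#: analysis band for L1NS, Hz (inclusive at both edges)
L1NS_BAND = (1.0, 5.0)
#: invalid runs up to this length are bridged by linear interpolation
MAX_INTERP_GAP_S = 0.5
#: minimum fraction of valid samples for an epoch to be usable
MIN_VALID_FRACTION = 0.5


@dataclass
class PupilEpoch:
    """Uniformly sampled pupil-diameter epoch for one eye.

    ``diameter`` is in mm; ``fs`` in Hz must exceed twice the upper analysis
    frequency (5 Hz). ``valid`` flags blink/track-loss samples.
    """

    t: np.ndarray
    diameter: np.ndarray
    eye: str
    fs: float
    valid: np.ndarray = None  # type: ignore[assignment]
    epoch_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.t) != len(self.diameter) or len(self.t) != len(self.valid):
            raise DegenerateInputError("epoch arrays must have equal length")
        if self.fs <= 2 * L1NS_BAND[1]:
            raise ParameterError(
                f"fs={self.fs} Hz must exceed twice the 5 Hz analysis limit"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(len(self.t) / self.fs)


@dataclass
class PupilMetricResult:
    """Per-epoch, per-eye metric bundle (all mm, all >= 0)."""

    l1ns: float
    stdp: float
    lpf: float
    eye: str
    epoch_id: str = ""


def epochs_from_gaze(gaze: TimeSeries, fs: float = 100.0) -> dict[str, PupilEpoch]:
    """Extract left/right pupil epochs from a gaze recording, resampled to fs."""
    out: dict[str, PupilEpoch] = {}
    for eye, col in (("left", "pupil_left_mm"), ("right", "pupil_right_mm")):
        rs = resample_uniform(gaze, fs, channels=[col])
        out[eye] = PupilEpoch(
            t=rs.t, diameter=rs.channels[col], eye=eye, fs=fs, valid=rs.valid(col)
        )
    return out


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive invalid samples."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def preprocess_pupil(
    epoch: PupilEpoch, max_gap_s: float = MAX_INTERP_GAP_S
) -> list[PupilEpoch]:
    """Bridge short invalid runs and split the epoch at long ones.

    Invalid runs up to ``max_gap_s`` (blinks) are linearly interpolated from
    the neighbouring valid samples; longer runs split the epoch into
    independent sub-epochs, so the return value is a list (length 1 when no
    long gap exists). Epochs with <50% valid samples are rejected.

    Raises
    ------
    EpochRejectedError : fewer than 50% valid samples
    """
    n = len(epoch)
    if n == 0 or epoch.valid.mean() < MIN_VALID_FRACTION:
        frac = float(epoch.valid.mean()) if n else 0.0
        raise EpochRejectedError(
            f"epoch {epoch.epoch_id or '<unnamed>'}: only {frac:.0%} valid samples"
        )
    max_gap = int(round(max_gap_s * epoch.fs))
    d = epoch.diameter.copy()
    valid = epoch.valid.copy()
    split_at: list[tuple[int, int]] = []
    for i, j in _invalid_runs(valid):
        if (j - i) <= max_gap and i > 0 and j < n:
            d[i:j] = np.interp(
                epoch.t[i:j], [epoch.t[i - 1], epoch.t[j]], [d[i - 1], d[j]]
            )
            valid[i:j] = True
        else:
            split_at.append((i, j))
    if not split_at:
        return [
            PupilEpoch(epoch.t, d, epoch.eye, epoch.fs, valid, epoch.epoch_id)
        ]
    pieces: list[PupilEpoch] = []
    prev = 0
    bounds = split_at + [(n, n)]
    for k, (i, j) in enumerate(bounds):
        if i > prev:
            pieces.append(
                PupilEpoch(
                    epoch.t[prev:i],
                    d[prev:i],
                    epoch.eye,
                    epoch.fs,
                    valid[prev:i],
                    f"{epoch.epoch_id}/part{k}" if epoch.epoch_id else f"part{k}",
                )
            )
        prev = j
    return pieces


def l1ns(
    epoch: PupilEpoch,
    band: tuple[float, float] = L1NS_BAND,
    window: str | None = None,
    mode: str = "amplitude",
) -> float:
    """L1 Norm of Spectrum: summed single-sided FFT components in ``band``.

    The mean-subtracted diameter is transformed with an epoch-length FFT; the
    single-sided spectrum uses 2/N amplitude scaling (DC and Nyquist bins
    unscaled) so a sinusoid of amplitude a contributes a at its bin. Bins with
    band[0] <= f <= band[1] (inclusive) are summed. ``mode='power'`` sums
    squared amplitudes instead.

    Raises
    ------
    DegenerateInputError : epoch shorter than 2 s (needs two cycles of 1 Hz)
    """
    if epoch.duration < 2.0:
        raise DegenerateInputError(
            f"l1ns needs >=2 s of data, got {epoch.duration:.3g} s"
        )
    y = epoch.diameter - epoch.diameter.mean()
    n = len(y)
    if window is not None:
        w = sps.get_window(window, n)
        y = y * w / w.mean()  # preserve amplitude of in-band tones on average
    spec = np.abs(np.fft.rfft(y))
    amp = spec * 2.0 / n
    amp[0] = spec[0] / n
    if n % 2 == 0:
        amp[-1] = spec[-1] / n
    f = np.fft.rfftfreq(n, d=1.0 / epoch.fs)
    sel = (f >= band[0]) & (f <= band[1])
    if mode == "amplitude":
        return float(amp[sel].sum())
    if mode == "power":
        return float((amp[sel] ** 2).sum())
    raise ParameterError(f"unknown l1ns mode {mode!r}")


def stdp(epoch: PupilEpoch) -> float:
    """Sample standard deviation (n-1 denominator) of pupil diameter, mm."""
    if len(epoch) < 2:
        raise DegenerateInputError("stdp needs >=2 samples")
    return float(np.std(epoch.diameter, ddof=1))


def lpf_metric(epoch: PupilEpoch, cutoff: float = 4.0, order: int = 4) -> float:
    """Mean |low-pass-filtered, mean-subtracted diameter|, mm.

    A zero-phase Butterworth low-pass (``order`` applied forward and backward)
    keeps the slow task-evoked component; the scalar is its mean absolute
    value.

    Raises
    ------
    ParameterError : cutoff at or above the Nyquist frequency
    """
    if cutoff >= epoch.fs / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below Nyquist {epoch.fs / 2} Hz"
        )
    y = epoch.diameter - epoch.diameter.mean()
    if len(y) < 3 * (order + 1):
        raise DegenerateInputError("epoch too short for zero-phase filtering")
    sos = sps.butter(order, cutoff, btype="low", fs=epoch.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, y)
    return float(np.mean(np.abs(filtered)))


def compute_pupil_metrics(
    epoch: PupilEpoch, min_part_s: float = 2.0
) -> PupilMetricResult | None:
    """Preprocess an epoch and compute all three metrics.

    Sub-epochs produced by long-gap splitting are weighted by duration when
    aggregating. Returns None (with a warning) when no usable piece remains.
    """
    try:
        pieces = preprocess_pupil(epoch)
    except EpochRejectedError as exc:
        warnings.warn(str(exc), stacklevel=2)
        return None
    pieces = [p for p in pieces if p.duration >= min_part_s]
    if not pieces:
        warnings.warn(
            f"epoch {epoch.epoch_id or '<unnamed>'}: no piece >= {min_part_s} s",
            stacklevel=2,
        )
        return None
    wts = np.array([p.duration for p in pieces])
    wts = wts / wts.sum()
    vals = np.array([[l1ns(p), stdp(p), lpf_metric(p)] for p in pieces])
    agg = wts @ vals
    return PupilMetricResult(
        l1ns=float(agg[0]),
        stdp=float(agg[1]),
        lpf=float(agg[2]),
        eye=epoch.eye,
        epoch_id=epoch.epoch_id,
    )
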