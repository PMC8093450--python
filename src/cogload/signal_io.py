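"""Recording I/O, event segmentation, resampling, and outer-fence outlier removal.

All recordings are plain CSV with a leading ``t_s`` column (seconds, strictly
increasing). Five schemas are supported:

========== ==================================================================
schema     columns
========== ==================================================================
gaze       t_s, gaze_x_deg, gaze_y_deg, pupil_left_mm, pupil_right_mm,
           valid_left, valid_right
eeg        t_s, AF3_uV, AF4_uV, T7_uV, T8_uV, Pz_uV
inceptor   t_s, defl_mm
flight     t_s, altitude_ft, airspeed_kt
events     t_s, kind, label
========== ==================================================================

Invalid samples are flagged, never silently dropped; downstream metric code
decides whether to interpolate, split, or reject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cogload.errors import DataError, DegenerateInputError, SchemaError

__all__ = [
    "TimeSeries",
    "EventLog",
    "SCHEMAS",
    "read_recording",
    "write_recording",
    "segment_by_events",
    "resample_uniform",
    "outer_fence_filter",
]

#: columns required by each recording schema (beyond t_s)
SCHEMAS: dict[str, list[str]] = {
    "gaze": [
        "gaze_x_deg",
        "gaze_y_deg",
        "pupil_left_mm",
        "pupil_right_mm",
        "valid_left",
        "valid_right",
    ],
    "eeg": ["AF3_uV", "AF4_uV", "T7_uV", "T8_uV", "Pz_uV"],
    "inceptor": ["defl_mm"],
    "flight": ["altitude_ft", "airspeed_kt"],
    "events": ["kind", "label"],
}

EVENT_KINDS = {"stimulus", "response", "segment_start", "segment_end"}


@dataclass
class TimeSeries:
    """Multi-channel sampled signal with per-sample validity flags.

    Parameters
    ----------
    t : array of float
        Timestamps in seconds, strictly increasing.
    channels : mapping of str -> array
        Named channel values, each the same length as ``t``. Units are carried
        in the channel name suffix (``_mm``, ``_deg``, ``_uV``, ``_ft``, ``_kt``).
    validity : mapping of str -> bool array, optional
        Per-channel validity. Channels absent from the mapping are fully valid.
    fs_nominal : float, optional
        Declared sampling rate in Hz. Checked against the median interval.
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    validity: dict[str, np.ndarray] = field(default_factory=dict)
    fs_nominal: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.validity = {k: np.asarray(v, dtype=bool) for k, v in self.validity.items()}
        n = len(self.t)
        for name, v in self.channels.items():
            if len(v) != n:
                raise DataError(f"channel {name!r} has {len(v)} rows, expected {n}")
        for name, v in self.validity.items():
            if name not in self.channels:
                raise DataError(f"validity flag for unknown channel {name!r}")
            if len(v) != n:
                raise DataError(f"validity for {name!r} has {len(v)} rows, expected {n}")
        if n > 1:
            dt = np.diff(self.t)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise DataError(f"non-monotone timestamp at row {int(bad[0]) + 1}")
            if self.fs_nominal is not None:
                fs_emp = 1.0 / float(np.median(dt))
                if not (0.9 * self.fs_nominal <= fs_emp <= 1.1 * self.fs_nominal):
                    raise DataError(
                        f"nominal rate {self.fs_nominal} Hz is >10% off the "
                        f"median empirical rate {fs_emp:.3g} Hz"
                    )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Elapsed time t[-1] - t[0] in seconds (0 for <2 samples)."""
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    def valid(self, channel: str) -> np.ndarray:
        """Validity mask for ``channel`` (all-True when no flag is stored)."""
        if channel in self.validity:
            return self.validity[channel]
        return np.ones(len(self.t), dtype=bool)

    def slice_time(self, t0: float, t1: float) -> "TimeSeries":
        """Sub-series over the closed interval [t0, t1]."""
        m = (self.t >= t0) & (self.t <= t1)
        return TimeSeries(
            t=self.t[m],
            channels={k: v[m] for k, v in self.channels.items()},
            validity={k: v[m] for k, v in self.validity.items()},
            fs_nominal=self.fs_nominal,
        )


@dataclass
class EventLog:
    """Timestamped experiment events (stimuli, responses, segment markers)."""

    t: np.ndarray
    kind: list[str]
    label: list[str]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if len(self.t) != len(self.kind) or len(self.t) != len(self.label):
            raise DataError("events: t, kind, label must have equal length")
        if np.any(np.diff(self.t) < 0):
            raise DataError("events: timestamps must be nondecreasing")
        unknown = set(self.kind) - EVENT_KINDS
        if unknown:
            raise DataError(f"events: unknown kinds {sorted(unknown)}")
        # every segment_start needs a matching segment_end with the same label
        open_segs: dict[str, int] = {}
        for k, lab in zip(self.kind, self.label):
            if k == "segment_start":
                open_segs[lab] = open_segs.get(lab, 0) + 1
            elif k == "segment_end":
                if open_segs.get(lab, 0) <= 0:
                    raise DataError(f"events: segment_end {lab!r} without start")
                open_segs[lab] -= 1
        dangling = [lab for lab, c in open_segs.items() if c > 0]
        if dangling:
            raise DataError(f"events: unmatched segment_start {dangling}")

    def __len__(self) -> int:
        return len(self.t)

    def segments(self, label: str) -> list[tuple[float, float]]:
        """(start, end) pairs for all segments with the given label, in log order."""
        out: list[tuple[float, float]] = []
        start: float | None = None
        for t, k, lab in zip(self.t, self.kind, self.label):
            if lab != label:
                continue
            if k == "segment_start":
                start = float(t)
            elif k == "segment_end" and start is not None:
                out.append((start, float(t)))
                start = None
        return out


def _require_columns(df: pd.DataFrame, schema: str, path: Path) -> None:
    missing = [c for c in ["t_s"] + SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} for schema {schema!r}"
        )


def read_recording(path: str | Path, schema: str) -> TimeSeries | EventLog:
    """Read and validate one CSV recording.

    Parameters
    ----------
    path : path to the CSV file
    schema : one of ``gaze``, ``eeg``, ``inceptor``, ``flight``, ``events``

    Returns
    -------
    TimeSeries (signal schemas) or EventLog (``events``).

    Raises
    ------
    SchemaError : unknown schema or missing column (named in the message)
    DataError : non-monotone timestamps (row index in the message)
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    _require_columns(df, schema, path)

    if schema == "events":
        return EventLog(
            t=df["t_s"].to_numpy(float),
            kind=[str(k) for k in df["kind"]],
            label=[str(l) for l in df["label"]],
        )

    t = df["t_s"].to_numpy(float)
    channels: dict[str, np.ndarray] = {}
    validity: dict[str, np.ndarray] = {}
    for col in SCHEMAS[schema]:
        if col.startswith("valid_"):
            continue
        channels[col] = df[col].to_numpy(float)
    if schema == "gaze":
        vl = df["valid_left"].to_numpy().astype(bool)
        vr = df["valid_right"].to_numpy().astype(bool)
        validity["pupil_left_mm"] = vl
        validity["pupil_right_mm"] = vr
        # gaze coordinates require both eyes tracked
        validity["gaze_x_deg"] = vl & vr
        validity["gaze_y_deg"] = vl & vr
    # NaNs in any signal channel are invalid regardless of flags
    for name, vals in channels.items():
        finite = np.isfinite(vals)
        if not finite.all():
            validity[name] = validity.get(name, np.ones(len(t), bool)) & finite
    return TimeSeries(t=t, channels=channels, validity=validity)


def write_recording(series: TimeSeries | EventLog, path: str | Path, schema: str) -> None:
    """Write a recording back to the CSV dialect :func:`read_recording` accepts."""
    path = Path(path)
    if schema == "events":
        assert isinstance(series, EventLog)
        pd.DataFrame({"t_s": series.t, "kind": series.kind, "label": series.label}).to_csv(
            path, index=False
        )
        return
    assert isinstance(series, TimeSeries)
    data: dict[str, np.ndarray] = {"t_s": series.t}
    for col in SCHEMAS[schema]:
        if col.startswith("valid_"):
            continue
        data[col] = series.channels[col]
    if schema == "gaze":
        data["valid_left"] = series.valid("pupil_left_mm").astype(int)
        data["valid_right"] = series.valid("pupil_right_mm").astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def segment_by_events(
    series: TimeSeries, log: EventLog, label: str
) -> list[TimeSeries]:
    """Cut a series into the [start, end] segments carrying ``label``.

    Boundary samples are included (closed intervals). Segments extending past
    the recording end are truncated with a warning. A label with no matching
    segments yields an empty list with a warning, not an exception.
    """
    pairs = log.segments(label)
    if not pairs:
        warnings.warn(f"no segments labelled {label!r} in event log", stacklevel=2)
        return []
    out = []
    t_end = series.t[-1] if len(series) else -np.inf
    for start, end in pairs:
        if end > t_end:
            warnings.warn(
                f"segment {label!r} [{start}, {end}] extends past recording end "
                f"{t_end}; truncated",
                stacklevel=2,
            )
        out.append(series.slice_time(start, end))
    return out


def resample_uniform(
    series: TimeSeries, fs: float, channels: Sequence[str] | None = None
) -> TimeSeries:
    """Linearly resample selected channels onto a uniform grid at ``fs`` Hz.

    Interpolation uses only valid samples of each channel; grid points that
    fall in stretches with no valid neighbours on one side take the nearest
    valid value. The returned validity marks grid points whose nearest
    original sample was invalid, so gap structure survives resampling.
    """
    if len(series) < 2:
        raise DegenerateInputError("resample_uniform needs >=2 samples")
    names = list(channels) if channels is not None else list(series.channels)
    t0, t1 = float(series.t[0]), float(series.t[-1])
    n = int(np.floor((t1 - t0) * fs)) + 1
    tg = t0 + np.arange(n) / fs
    out_ch: dict[str, np.ndarray] = {}
    out_val: dict[str, np.ndarray] = {}
    for name in names:
        v = series.channels[name]
        ok = series.valid(name) & np.isfinite(v)
        if ok.sum() < 2:
            out_ch[name] = np.full(n, np.nan)
            out_val[name] = np.zeros(n, bool)
            continue
        out_ch[name] = np.interp(tg, series.t[ok], v[ok])
        # validity: nearest original sample valid?
        idx = np.searchsorted(series.t, tg)
        idx = np.clip(idx, 1, len(series.t) - 1)
        left, right = idx - 1, idx
        nearest = np.where(
            np.abs(tg - series.t[left]) <= np.abs(series.t[right] - tg), left, right
        )
        out_val[name] = ok[nearest]
    return TimeSeries(t=tg, channels=out_ch, validity=out_val, fs_nominal=fs)


def outer_fence_filter(
    x: np.ndarray | Sequence[float], multiplier: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Remove values outside the Tukey outer fences [Q1 - m*IQR, Q3 + m*IQR].

    Quartiles use linear interpolation of the empirical CDF (numpy's default,
    type-7). Non-finite values are always marked removed. Order is preserved.

    Returns
    -------
    kept : values inside the fences, original order
    removed_mask : boolean mask over the input, True where removed

    Raises
    ------
    DegenerateInputError : fewer than 4 finite values
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise DegenerateInputError(
            f"outer_fence_filter needs >=4 finite values, got {int(finite.sum())}"
        )
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    inside = finite & (x >= lo) & (x <= hi)
    return x[inside], ~inside
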