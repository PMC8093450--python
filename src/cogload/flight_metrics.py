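"""Pilot-performance metrics from inceptor and flight-state traces.

Duty cycle (DC) is the percentage of time the inceptor is actively moved: an
inter-sample interval counts as active when the deflection rate reaches a
noise threshold or the stick is held at full deflection. Aggressiveness is
the mean squared deflection rate, (mm/s)^2. Tracking performance is the RMSE
of altitude/airspeed about the task reference, expressed as a percentage of
the reference value. Higher workload shows up as higher DC and larger
tracking error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cogload.errors import DataError, DegenerateInputError
from cogload.signal_io import TimeSeries

__all__ = [
    "InceptorTrace",
    "PIWPoint",
    "FlightReference",
    "duty_cycle",
    "aggressiveness",
    "piw_point",
    "rmse_percent",
]

#: default deflection-rate noise threshold, mm/s
NOISE_THRESHOLD = 0.5
#: default full-scale stick deflection, mm
DELTA_MAX = 80.0


@dataclass
class InceptorTrace:
    """Stick deflection trace: timestamps (s), deflection (mm), full scale (mm)."""

    t: np.ndarray
    defl: np.ndarray
    delta_max: float = DELTA_MAX
    noise_threshold: float = NOISE_THRESHOLD

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.defl = np.asarray(self.defl, dtype=float)
        if len(self.t) != len(self.defl):
            raise DataError("inceptor trace: t and defl must have equal length")
        if self.noise_threshold <= 0:
            raise DataError("noise_threshold must be positive")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise DataError("inceptor trace: timestamps must be strictly increasing")

    @classmethod
    def from_timeseries(
        cls,
        series: TimeSeries,
        delta_max: float = DELTA_MAX,
        noise_threshold: float = NOISE_THRESHOLD,
    ) -> "InceptorTrace":
        return cls(series.t, series.channels["defl_mm"], delta_max, noise_threshold)


@dataclass
class PIWPoint:
    """One point of the pilot-inceptor-workload plot."""

    aggressiveness: float  # (mm/s)^2
    duty_cycle: float  # percent


@dataclass
class FlightReference:
    """Task reference: altitude band (ft) and trim airspeed (knots)."""

    altitude_band: tuple[float, float] = (4000.0, 5000.0)
    airspeed_kt: float = 120.0

    def __post_init__(self) -> None:
        lo, hi = self.altitude_band
        if not lo < hi:
            raise DataError("altitude band lo must be < hi")

    def target(self, channel: str) -> float:
        if channel == "altitude":
            return 0.5 * (self.altitude_band[0] + self.altitude_band[1])
        if channel == "airspeed":
            return self.airspeed_kt
        raise DataError(f"unknown flight channel {channel!r}")


def _activity(trace: InceptorTrace) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval activity flags x_i and interval lengths dt_i (i = 2..n)."""
    dt = np.diff(trace.t)
    rate = np.abs(np.diff(trace.defl)) / dt
    saturated = np.abs(trace.defl[1:]) >= trace.delta_max
    x = ((rate >= trace.noise_threshold) | saturated).astype(float)
    return x, dt


def duty_cycle(trace: InceptorTrace, strict_printed: bool = False) -> float:
    """Percentage of time with active inceptor input, in [0, 100].

    An interval is idle when its absolute deflection rate is below the noise
    threshold and the stick is off the stops; otherwise active. The default is
    time-weighted, 100 * sum(x_i * dt_i) / (t_n - t_1), so a fully active
    trace is exactly 100%. ``strict_printed=True`` instead returns
    100 * sum(x_i) / (t_n - t_2), the unweighted per-sample count over the
    elapsed time from the second sample (not a percentage of time unless the
    sampling is uniform and dense).
    """
    if len(trace.t) < 3:
        raise DegenerateInputError("duty_cycle needs >=3 samples")
    x, dt = _activity(trace)
    if strict_printed:
        return 100.0 * float(x.sum()) / float(trace.t[-1] - trace.t[1])
    return 100.0 * float((x * dt).sum()) / float(trace.t[-1] - trace.t[0])


def aggressiveness(trace: InceptorTrace) -> float:
    """Mean squared deflection rate, (1/(n-1)) * sum((d(i)-d(i-1))/(t(i)-t(i-1)))^2."""
    if len(trace.t) < 2:
        raise DegenerateInputError("aggressiveness needs >=2 samples")
    dt = np.diff(trace.t)
    rate = np.diff(trace.defl) / dt
    return float(np.mean(rate**2))


def piw_point(trace: InceptorTrace) -> PIWPoint:
    """Aggressiveness vs duty cycle for one trace (one PIW-plot point)."""
    return PIWPoint(aggressiveness=aggressiveness(trace), duty_cycle=duty_cycle(trace))


def rmse_percent(
    trace: TimeSeries, ref: FlightReference, channel: str
) -> float:
    """RMSE about the task reference as a percentage of the reference.

    ``channel`` is ``altitude`` (target = band midpoint, ft) or ``airspeed``
    (target = trim value, knots).
    """
    col = {"altitude": "altitude_ft", "airspeed": "airspeed_kt"}.get(channel)
    if col is None:
        raise DataError(f"unknown flight channel {channel!r}")
    if len(trace) == 0:
        raise DegenerateInputError("rmse_percent: empty trace")
    target = ref.target(channel)
    if target <= 0:
        raise DataError("reference target must be positive")
    v = trace.channels[col]
    ok = trace.valid(col) & np.isfinite(v)
    if not ok.any():
        raise DegenerateInputError("rmse_percent: no valid samples")
    rmse = float(np.sqrt(np.mean((v[ok] - target) ** 2)))
    return 100.0 * rmse / target
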