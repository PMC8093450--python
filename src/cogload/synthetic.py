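"""Synthetic multi-condition workload studies with known ground truth.

A scalar workload level in [0, 1] modulates exactly the signal properties the
metric modules measure: the 1-5 Hz pupil-diameter component, the spatial
dispersion of gaze fixations, EEG band amplitudes, the fraction of time the
inceptor is actively moved, the altitude/airspeed tracking error, and the
saccadic-intrusion rate. Signal models are intentionally minimal (sinusoid
banks, cluster point processes, AR(1) errors plus noise) so that each
metric's driving property is independently tunable through the effect map;
physiological realism is explicitly not a goal. With all gains zero the
conditions are statistically identical - the calibration null.

All randomness flows through numpy's PCG64 ``default_rng``; a study is fully
reproducible from its integer seed, with per-recording streams derived via
``SeedSequence`` so outputs are stable regardless of generation order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
from pydantic import BaseModel, Field, field_validator

from cogload.flight_metrics import DELTA_MAX, NOISE_THRESHOLD, InceptorTrace
from cogload.pupil_metrics import PupilEpoch
from cogload.signal_io import EventLog, TimeSeries, write_recording
from cogload.stats import ConfusionCounts

__all__ = [
    "Condition",
    "EffectMap",
    "StudyConfig",
    "gen_pupil",
    "gen_gaze",
    "gen_eeg",
    "gen_inceptor_flight",
    "gen_nback_log",
    "gen_study",
]


class Condition(BaseModel):
    """One task condition: a label and its latent workload level."""

    name: str
    workload: float = Field(ge=0.0, le=1.0)


class EffectMap(BaseModel):
    """Per-metric gain of the latent workload on the generated signals.

    A gain g scales the driven quantity as base * (1 + g * workload); setting
    every gain to 0 yields the exact null study (identical conditions).
    """

    pupil_band_gain: float = Field(default=1.5, ge=0)
    gaze_dispersion_gain: float = Field(default=2.5, ge=0)
    theta_gain: float = Field(default=0.8, ge=0)
    alpha_gain: float = Field(default=0.6, ge=0)
    low_beta_gain: float = Field(default=0.8, ge=0)
    high_beta_gain: float = Field(default=0.7, ge=0)
    inceptor_activity_gain: float = Field(default=1.8, ge=0)
    tracking_error_gain: float = Field(default=1.5, ge=0)
    si_rate_gain: float = Field(default=0.0, ge=0)
    si_velocity_gain: float = Field(default=0.0, ge=0)

    @classmethod
    def null(cls) -> "EffectMap":
        """All gains zero: conditions become statistically identical."""
        return cls(**{name: 0.0 for name in cls.model_fields})


class StudyConfig(BaseModel):
    """Recipe for a synthetic study.

    Defaults mirror the flight-simulator design: 12 participants, three
    conditions C1/C2/C3 of increasing demand (C3 adds a secondary task), a
    240 s recording per cell, gaze/pupil at 100 Hz, 5-channel EEG at 128 Hz.
    """

    participants: int = Field(default=12, ge=1)
    conditions: list[Condition] = Field(
        default_factory=lambda: [
            Condition(name="C1", workload=0.25),
            Condition(name="C2", workload=0.45),
            Condition(name="C3", workload=0.90),
        ]
    )
    duration_s: float = Field(default=240.0, gt=0)
    fs_gaze: float = Field(default=100.0, ge=50)
    fs_eeg: float = Field(default=128.0, ge=64)
    fs_inceptor: float = Field(default=50.0, ge=10)
    fs_flight: float = Field(default=10.0, gt=0)
    seed: int = 0
    effects: EffectMap = Field(default_factory=EffectMap)

    @field_validator("conditions")
    @classmethod
    def _distinct_names(cls, v: list[Condition]) -> list[Condition]:
        names = [c.name for c in v]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be distinct")
        return v


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# pupil


def gen_pupil(
    workload: float,
    duration: float,
    fs: float = 100.0,
    seed: int | np.random.Generator = 0,
    band_gain: float = 1.5,
    base_amplitude: float = 0.08,
    baseline_mm: float = 3.0,
    noise_sd: float = 0.01,
    blink_rate: float = 0.05,
    drift_amplitude: float = 0.15,
) -> tuple[PupilEpoch, PupilEpoch]:
    """Left/right pupil-diameter epochs with workload-driven 1-5 Hz power.

    The diameter is baseline + slow drift (<0.2 Hz) + a bank of 1-5 Hz
    sinusoids with total amplitude base_amplitude * (1 + band_gain * workload)
    + white noise. Left and right share the deterministic components and the
    bulk of the noise (correlation about 0.9). Blinks appear as invalid runs
    of 100-300 ms at ``blink_rate`` per second.
    """
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    drift_f = rng.uniform(0.03, 0.15)
    drift = drift_amplitude * np.sin(2 * np.pi * drift_f * t + rng.uniform(0, 2 * np.pi))
    amp_total = base_amplitude * (1.0 + band_gain * workload)
    band = np.zeros(n)
    freqs = rng.uniform(1.2, 4.8, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    for f0, ph in zip(freqs, phases):
        band += (amp_total / 4.0) * np.sin(2 * np.pi * f0 * t + ph)
    shared_noise = rng.normal(0, noise_sd, n)
    common = baseline_mm + drift + band + 0.9 * shared_noise

    epochs = []
    for eye in ("left", "right"):
        d = common + rng.normal(0, noise_sd * 0.45, n)
        valid = np.ones(n, dtype=bool)
        n_blinks = rng.poisson(blink_rate * duration)
        for _ in range(n_blinks):
            start = rng.uniform(0, duration)
            width = rng.uniform(0.1, 0.3)
            valid[(t >= start) & (t < start + width)] = False
        epochs.append(PupilEpoch(t=t, diameter=d, eye=eye, fs=fs, valid=valid))
    return epochs[0], epochs[1]


# ---------------------------------------------------------------------------
# gaze


def gen_gaze(
    workload: float,
    duration: float,
    fs: float = 100.0,
    seed: int | np.random.Generator = 0,
    dispersion_gain: float = 2.5,
    si_rate_gain: float = 0.0,
    base_spread: float = 0.4,
    base_si_rate: float = 0.15,
    n_clusters: int = 4,
    noise_sd: float = 0.02,
) -> tuple[TimeSeries, dict[str, Any]]:
    """Gaze trace from a clustered fixation process with planted intrusions.

    Fixation targets come from ``n_clusters`` scan points; the per-cluster
    spread grows as base_spread * (1 + dispersion_gain * workload) and the
    probability of jumping to a different cluster rises with workload, so
    fixations disperse toward spatial randomness under load. Dwell times are
    uniform on [200, 800] ms; saccades are 20-40 ms linear transitions.
    Saccadic intrusions (triangular out-and-back excursions on x, amplitude
    0.6-1.2 deg, duration 150-400 ms) are planted at
    base_si_rate * (1 + si_rate_gain * workload) per second.

    Returns the gaze TimeSeries and a ground-truth dict with the generated
    fixations and planted SI events.
    """
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # fixed scan layout (out-the-window view, primary flight display,
    # navigation display, secondary display) with small per-recording jitter
    layout = np.array([[-6.0, 4.0], [6.0, 4.0], [-6.0, -4.0], [6.0, -4.0]])
    reps = int(np.ceil(n_clusters / len(layout)))
    centers = np.tile(layout, (reps, 1))[:n_clusters] + rng.normal(0, 0.3, (n_clusters, 2))
    spread = base_spread * (1.0 + dispersion_gain * workload)
    p_jump = min(0.95, 0.15 + 0.6 * workload)

    x = np.zeros(n)
    y = np.zeros(n)
    truth_fixations: list[dict[str, float]] = []
    cluster = int(rng.integers(n_clusters))
    pos = centers[cluster] + rng.normal(0, spread, 2)
    prev_x = np.inf  # x of the fixation before the current one
    # min jump 1.5 deg: even the transition's boundary samples then move at
    # >= 37.5 deg/s by central difference, safely above the 30 deg/s I-VT
    # threshold, so every generated transition classifies as a saccade
    # regardless of workload
    min_jump = 1.5
    i = 0
    while i < n:
        dwell = rng.uniform(0.2, 0.8)
        n_dwell = max(1, int(round(dwell * fs)))
        j = min(n, i + n_dwell)
        x[i:j] = pos[0]
        y[i:j] = pos[1]
        truth_fixations.append(
            {"start": t[i], "end": t[j - 1], "fx": float(pos[0]), "fy": float(pos[1])}
        )
        if j >= n:
            break
        if rng.random() < p_jump:
            cluster = int(rng.integers(n_clusters))
        new_pos = centers[cluster] + rng.normal(0, spread, 2)
        # enforce a saccade-sized jump, and never an immediate horizontal
        # return to the previous fixation (a there-and-back through one
        # fixation would satisfy the saccadic-intrusion definition)
        for _ in range(20):
            step = new_pos - pos
            dist = float(np.hypot(*step))
            if dist >= min_jump and abs(new_pos[0] - prev_x) > 0.7:
                break
            if dist < min_jump:
                direction = step / dist if dist > 1e-9 else rng.normal(0, 1, 2)
                direction = direction / np.hypot(*direction)
                new_pos = pos + direction * rng.uniform(min_jump, min_jump + 1.0)
            if abs(new_pos[0] - prev_x) <= 0.7:
                new_pos = centers[cluster] + rng.normal(0, max(spread, 0.6), 2)
        # saccade: fixed 20 ms transition; a duration independent of
        # amplitude keeps the fixation-time share free of workload signal,
        # and even a 1 deg jump then moves at 50 deg/s (above the I-VT cut)
        n_sac = max(2, int(round(0.02 * fs)))
        k = min(n, j + n_sac)
        frac = np.linspace(0, 1, k - j, endpoint=False)
        x[j:k] = pos[0] + frac * (new_pos[0] - pos[0])
        y[j:k] = pos[1] + frac * (new_pos[1] - pos[1])
        prev_x = float(pos[0])
        pos = new_pos
        i = k

    # plant saccadic intrusions inside fixation stretches
    si_rate = base_si_rate * (1.0 + si_rate_gain * workload)
    n_si = rng.poisson(si_rate * duration)
    planted: list[dict[str, float]] = []
    candidates = [f for f in truth_fixations if (f["end"] - f["start"]) >= 0.75]
    rng.shuffle(candidates)
    spans: list[tuple[float, float]] = []
    for f in candidates:
        if len(planted) >= n_si:
            break
        amp = rng.uniform(0.6, 1.2)
        dur = rng.uniform(0.15, min(0.4, f["end"] - f["start"] - 0.45))
        start = f["start"] + 0.30  # quiet stretch so the baseline stabilises
        too_close = any(start < e + 1.0 and s < start + dur + 1.0 for s, e in spans)
        if too_close or start + dur > f["end"]:
            continue
        sign = rng.choice([-1.0, 1.0])
        sel = (t >= start) & (t < start + dur)
        tt = t[sel]
        tri = 1.0 - np.abs((tt - start) / dur * 2.0 - 1.0)  # 0 -> 1 -> 0
        x[sel] += sign * amp * tri
        planted.append(
            {
                "onset": float(start),
                "duration": float(dur),
                "amplitude": float(amp),
                "velocity": float(2.0 * amp / dur),
            }
        )
        spans.append((start, start + dur))

    x += rng.normal(0, noise_sd, n)
    y += rng.normal(0, noise_sd, n)
    series = TimeSeries(
        t=t, channels={"gaze_x_deg": x, "gaze_y_deg": y}, fs_nominal=fs
    )
    truth = {"fixations": truth_fixations, "si_events": planted, "spread": spread}
    return series, truth


# ---------------------------------------------------------------------------
# EEG


#: baseline per-band component amplitude, uV
_EEG_BASE_AMP = {"theta": 4.0, "alpha": 5.0, "low_beta": 3.0, "high_beta": 2.0}
_EEG_BAND_RANGES = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "low_beta": (13.0, 21.0),
    "high_beta": (21.0, 30.0),
}
EEG_CHANNELS = ("AF3_uV", "AF4_uV", "T7_uV", "T8_uV", "Pz_uV")


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-power background noise via spectral shaping."""
    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std() * sd


def gen_eeg(
    workload: float,
    duration: float,
    fs: float = 128.0,
    channels: tuple[str, ...] = EEG_CHANNELS,
    seed: int | np.random.Generator = 0,
    band_gains: dict[str, float] | None = None,
    background_sd: float = 3.0,
    channel_scale_sd: float = 0.1,
) -> TimeSeries:
    """Multi-channel EEG with workload-scaled band-limited components.

    Each band contributes a bank of sinusoids inside its range with total
    amplitude base * (1 + gain * workload), on top of a 1/f background.
    Channels share 70% of every component (common cortical source) plus an
    independent remainder and a per-channel gain.
    """
    rng = _rng(seed)
    if band_gains is None:
        band_gains = {b: 0.8 for b in _EEG_BASE_AMP}
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    def band_component(r: np.random.Generator) -> np.ndarray:
        out = np.zeros(n)
        for band, (lo, hi) in _EEG_BAND_RANGES.items():
            amp = _EEG_BASE_AMP[band] * (1.0 + band_gains.get(band, 0.0) * workload)
            freqs = r.uniform(lo + 0.2, hi - 0.2, size=5)
            phases = r.uniform(0, 2 * np.pi, size=5)
            for f0, ph in zip(freqs, phases):
                out += (amp / 5.0) * np.sin(2 * np.pi * f0 * t + ph)
        return out

    shared = band_component(rng) + _pink_noise(rng, n, background_sd)
    data: dict[str, np.ndarray] = {}
    for ch in channels:
        own = band_component(rng) + _pink_noise(rng, n, background_sd)
        gain = rng.normal(1.0, channel_scale_sd)
        data[ch] = gain * (0.7 * shared + 0.3 * own)
    return TimeSeries(t=t, channels=data, fs_nominal=fs)


# ---------------------------------------------------------------------------
# inceptor + flight


def gen_inceptor_flight(
    workload: float,
    duration: float,
    fs: float = 50.0,
    seed: int | np.random.Generator = 0,
    activity_gain: float = 1.8,
    base_activity: float = 0.2,
    tracking_gain: float = 1.5,
    fs_flight: float = 10.0,
    altitude_target: float = 4500.0,
    airspeed_target: float = 120.0,
    base_alt_sd: float = 60.0,
    base_spd_sd: float = 4.0,
) -> tuple[InceptorTrace, TimeSeries, dict[str, Any]]:
    """Inceptor deflection and flight-state traces for one recording.

    The stick alternates idle holds and active bouts (piecewise ramps with
    |rate| well above the noise threshold); the active time fraction is
    a = base_activity * (1 + activity_gain * workload), capped at 0.95.
    Altitude and airspeed follow their targets plus AR(1) errors whose
    stationary SD scales as (1 + tracking_gain * workload). Returns the
    trace pair and a truth dict with the realised activity fraction.
    """
    rng = _rng(seed)
    a = min(0.95, base_activity * (1.0 + activity_gain * workload))
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    defl = np.zeros(n)
    active_mask = np.zeros(n, dtype=bool)
    mean_active = 2.0
    mean_idle = mean_active * (1.0 - a) / max(a, 1e-9) if a > 0 else np.inf

    i = 0
    pos = 0.0
    active = rng.random() < a
    while i < n:
        bout = rng.exponential(mean_active if active else mean_idle)
        bout = float(np.clip(bout, 0.3, 20.0))
        j = min(n, i + max(1, int(round(bout * fs))))
        if active and a > 0:
            k = i
            while k < j:
                ramp_n = min(j - k, max(1, int(round(rng.uniform(0.3, 0.8) * fs))))
                slope = rng.uniform(1.5, 8.0) * rng.choice([-1.0, 1.0])
                # reflect away from the stops
                if abs(pos) > 0.7 * DELTA_MAX:
                    slope = -np.sign(pos) * abs(slope)
                seg = pos + slope * (np.arange(1, ramp_n + 1) / fs)
                seg = np.clip(seg, -0.95 * DELTA_MAX, 0.95 * DELTA_MAX)
                defl[k : k + ramp_n] = seg
                pos = float(seg[-1])
                k += ramp_n
            active_mask[i:j] = True
        else:
            defl[i:j] = pos
        i = j
        active = not active if a > 0 else False

    trace = InceptorTrace(
        t=t, defl=defl, delta_max=DELTA_MAX, noise_threshold=NOISE_THRESHOLD
    )

    nf = int(round(duration * fs_flight))
    tf = np.arange(nf) / fs_flight
    def ar1(target: float, sd0: float, tau: float) -> np.ndarray:
        sd = sd0 * (1.0 + tracking_gain * workload)
        phi = np.exp(-1.0 / (fs_flight * tau))
        innov_sd = sd * np.sqrt(1.0 - phi**2)
        e = np.zeros(nf)
        e[0] = rng.normal(0, sd)
        w = rng.normal(0, innov_sd, nf)
        for k in range(1, nf):
            e[k] = phi * e[k - 1] + w[k]
        return target + e

    flight = TimeSeries(
        t=tf,
        channels={
            "altitude_ft": ar1(altitude_target, base_alt_sd, 20.0),
            "airspeed_kt": ar1(airspeed_target, base_spd_sd, 10.0),
        },
        fs_nominal=fs_flight,
    )
    truth = {
        "activity_fraction_target": a,
        "activity_fraction_realised": float(active_mask.mean()),
    }
    return trace, flight, truth


# ---------------------------------------------------------------------------
# psychometric task log


def gen_nback_log(
    p_hit: float,
    p_false_alarm: float,
    n_trials: int,
    level: int = 2,
    seed: int | np.random.Generator = 0,
    isi_s: float = 2.0,
) -> tuple[EventLog, ConfusionCounts]:
    """Scripted N-back session: stimulus stream plus response events.

    Digits 1-9 are presented every ``isi_s`` seconds; a trial is a target when
    the digit matches the one ``level`` steps back. The scripted responder
    presses on targets with probability ``p_hit`` and on non-targets with
    probability ``p_false_alarm``. Tallies: correct = hits, missed = unanswered
    targets, wrong = false alarms, avoid = correct rejections; they always sum
    to ``n_trials``.
    """
    if not (0 <= p_hit <= 1 and 0 <= p_false_alarm <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = _rng(seed)
    digits = rng.integers(1, 10, size=n_trials)
    ts: list[float] = []
    kinds: list[str] = []
    labels: list[str] = []
    counts = dict(correct=0, wrong=0, avoid=0, missed=0)
    ts.append(0.0)
    kinds.append("segment_start")
    labels.append(f"{level}-back")
    for i in range(n_trials):
        t0 = (i + 1) * isi_s
        ts.append(t0)
        kinds.append("stimulus")
        labels.append(str(int(digits[i])))
        is_target = i >= level and digits[i] == digits[i - level]
        responded = rng.random() < (p_hit if is_target else p_false_alarm)
        if responded:
            ts.append(t0 + float(rng.uniform(0.3, 0.9)))
            kinds.append("response")
            labels.append("press")
        if is_target:
            counts["correct" if responded else "missed"] += 1
        else:
            counts["wrong" if responded else "avoid"] += 1
    ts.append((n_trials + 1) * isi_s)
    kinds.append("segment_end")
    labels.append(f"{level}-back")
    return EventLog(t=np.array(ts), kind=kinds, label=labels), ConfusionCounts(**counts)


# ---------------------------------------------------------------------------
# whole study


def _cell_seed(base: int, p: int, c: int, modality: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=base, spawn_key=(p, c, modality))
    return np.random.default_rng(ss)


def gen_study(
    config: StudyConfig, out_dir: str | Path, force: bool = False
) -> dict[str, Any]:
    """Write a complete study (CSV recordings + manifest) to ``out_dir``.

    Layout: ``<out>/<participant>/<condition>/{gaze,eeg,inceptor,flight,
    events}.csv`` with one recording set per participant x condition, plus a
    ``manifest.json`` capturing the config and every realised ground-truth
    parameter. Deterministic byte-for-byte in ``config.seed``.

    Refuses a non-empty existing directory unless ``force`` is given.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    eff = config.effects
    band_gains = {
        "theta": eff.theta_gain,
        "alpha": eff.alpha_gain,
        "low_beta": eff.low_beta_gain,
        "high_beta": eff.high_beta_gain,
    }
    manifest: dict[str, Any] = {
        "config": json.loads(config.model_dump_json()),
        "recordings": {},
    }
    for p in range(config.participants):
        pid = f"p{p + 1:02d}"
        prng = _cell_seed(config.seed, p, 0, 99)
        baseline_mm = float(prng.normal(3.0, 0.25))
        for c, cond in enumerate(config.conditions):
            w = cond.workload
            cell_dir = out / pid / cond.name
            cell_dir.mkdir(parents=True, exist_ok=True)

            left, right = gen_pupil(
                w, config.duration_s, config.fs_gaze,
                seed=_cell_seed(config.seed, p, c, 0),
                band_gain=eff.pupil_band_gain, baseline_mm=baseline_mm,
            )
            gaze, gaze_truth = gen_gaze(
                w, config.duration_s, config.fs_gaze,
                seed=_cell_seed(config.seed, p, c, 1),
                dispersion_gain=eff.gaze_dispersion_gain,
                si_rate_gain=eff.si_rate_gain,
            )
            gaze_full = TimeSeries(
                t=gaze.t,
                channels={
                    "gaze_x_deg": gaze.channels["gaze_x_deg"],
                    "gaze_y_deg": gaze.channels["gaze_y_deg"],
                    "pupil_left_mm": left.diameter,
                    "pupil_right_mm": right.diameter,
                },
                validity={
                    "pupil_left_mm": left.valid,
                    "pupil_right_mm": right.valid,
                },
                fs_nominal=config.fs_gaze,
            )
            eeg = gen_eeg(
                w, config.duration_s, config.fs_eeg,
                seed=_cell_seed(config.seed, p, c, 2), band_gains=band_gains,
            )
            trace, flight, fly_truth = gen_inceptor_flight(
                w, config.duration_s, config.fs_inceptor,
                seed=_cell_seed(config.seed, p, c, 3),
                activity_gain=eff.inceptor_activity_gain,
                tracking_gain=eff.tracking_error_gain,
                fs_flight=config.fs_flight,
            )
            events = EventLog(
                t=np.array([0.0, float(gaze.t[-1])]),
                kind=["segment_start", "segment_end"],
                label=["task", "task"],
            )

            write_recording(gaze_full, cell_dir / "gaze.csv", "gaze")
            write_recording(eeg, cell_dir / "eeg.csv", "eeg")
            write_recording(
                TimeSeries(t=trace.t, channels={"defl_mm": trace.defl}),
                cell_dir / "inceptor.csv",
                "inceptor",
            )
            write_recording(flight, cell_dir / "flight.csv", "flight")
            write_recording(events, cell_dir / "events.csv", "events")

            manifest["recordings"][f"{pid}/{cond.name}"] = {
                "workload": w,
                "baseline_pupil_mm": baseline_mm,
                "n_planted_si": len(gaze_truth["si_events"]),
                "gaze_spread_deg": gaze_truth["spread"],
                **fly_truth,
            }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
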