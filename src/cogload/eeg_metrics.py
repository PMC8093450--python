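"""EEG band-power extraction over the five canonical bands.

Band power in the theta (4-8 Hz), alpha (8-13 Hz), low-beta (13-21 Hz) and
high-beta (21-30 Hz) ranges rises with task demand; gamma (31-100 Hz) is
defined but excluded from default reports (it sits largely above Nyquist at
the 128 Hz recording rate and showed no demand sensitivity). Power spectra
are Welch estimates (2 s Hann windows, 50% overlap, resolution 0.5 Hz) and
band power is the trapezoidal integral of the PSD over the band. Summaries
are medians pooled over channels and sliding epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from cogload.errors import DegenerateInputError, ParameterError
from cogload.signal_io import TimeSeries

__all__ = [
    "BandDefinition",
    "BANDS",
    "DEFAULT_BAND_NAMES",
    "Spectrum",
    "BandPowerSummary",
    "psd",
    "band_power",
    "band_power_summary",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ParameterError(f"band {self.name}: lo must be < hi")


#: canonical EEG bands, Hz
BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "low_beta": BandDefinition("low_beta", 13.0, 21.0),
    "high_beta": BandDefinition("high_beta", 21.0, 30.0),
    "gamma": BandDefinition("gamma", 31.0, 100.0),
}

#: bands included in default summaries (gamma excluded)
DEFAULT_BAND_NAMES = ("theta", "alpha", "low_beta", "high_beta")


@dataclass
class Spectrum:
    """One-sided power spectral density, uV^2/Hz."""

    f: np.ndarray
    pxx: np.ndarray

    @property
    def nyquist(self) -> float:
        return float(self.f[-1])


@dataclass
class BandPowerSummary:
    """Band powers per (channel, epoch) plus the pooled median per band."""

    per_channel: dict[tuple[str, int], dict[str, float]]  # (channel, epoch) -> band -> uV^2
    median: dict[str, float]  # band -> pooled median uV^2


def psd(
    channel_values: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> Spectrum:
    """Welch-averaged periodogram of one uniformly sampled channel.

    Frequency resolution is 1/window_s. Raises for recordings shorter than a
    single window.
    """
    x = np.asarray(channel_values, dtype=float)
    nperseg = int(round(window_s * fs))
    if len(x) < nperseg:
        raise DegenerateInputError(
            f"psd needs >= {window_s} s of data ({nperseg} samples), got {len(x)}"
        )
    f, pxx = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=int(nperseg * overlap)
    )
    return Spectrum(f=f, pxx=pxx)


def band_power(spectrum: Spectrum, band: BandDefinition | str) -> float:
    """Trapezoidal integral of the PSD over [band.lo, band.hi], uV^2.

    Bands reaching above Nyquist are clipped with a warning; a band entirely
    above Nyquist is an error.
    """
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band.lo, band.hi
    if lo >= spectrum.nyquist:
        raise ParameterError(
            f"band {band.name} ({lo}-{hi} Hz) lies entirely above Nyquist "
            f"{spectrum.nyquist} Hz"
        )
    if hi > spectrum.nyquist:
        warnings.warn(
            f"band {band.name} clipped at Nyquist {spectrum.nyquist} Hz", stacklevel=2
        )
        hi = spectrum.nyquist
    sel = (spectrum.f >= lo) & (spectrum.f <= hi)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(spectrum.pxx[sel], spectrum.f[sel]))


def band_power_summary(
    recording: TimeSeries,
    fs: float,
    bands: list[BandDefinition] | None = None,
    epoch_s: float = 10.0,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> BandPowerSummary:
    """Per-channel band powers over sliding epochs, pooled into a median per band.

    Epochs of ``epoch_s`` advance by half their length; each epoch's PSD is a
    Welch estimate with ``window_s`` windows. Channels whose samples are all
    invalid are skipped; an entirely invalid recording is an error.
    """
    if bands is None:
        bands = [BANDS[n] for n in DEFAULT_BAND_NAMES]
    n = len(recording)
    nep = int(round(epoch_s * fs))
    if n < nep:
        nep = n  # single shorter epoch
    step = max(1, nep // 2)
    per_channel: dict[tuple[str, int], dict[str, float]] = {}
    for name, vals in recording.channels.items():
        valid = recording.valid(name) & np.isfinite(vals)
        if not valid.any():
            continue
        x = np.where(valid, vals, np.nan)
        # bridge isolated invalid samples; epochs with >20% invalid are skipped
        if np.isnan(x).any():
            idx = np.arange(n)
            x = np.interp(idx, idx[valid], vals[valid])
        ep_i = 0
        for start in range(0, n - nep + 1, step):
            seg_valid = valid[start : start + nep]
            if seg_valid.mean() < 0.8:
                continue
            spec = psd(x[start : start + nep], fs, window_s=window_s, overlap=overlap)
            per_channel[(name, ep_i)] = {b.name: band_power(spec, b) for b in bands}
            ep_i += 1
    if not per_channel:
        raise DegenerateInputError("band_power_summary: no valid channel data")
    median = {
        b.name: float(np.median([v[b.name] for v in per_channel.values()]))
        for b in bands
    }
    return BandPowerSummary(per_channel=per_channel, median=median)
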