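"""Motorboat-noise detection from hydrophone recordings.

Pipeline: 16-bit PCM WAV -> calibrated pressure (uPa) -> per-second power
spectral density and sound pressure level -> basal-level thresholding ->
binary noise-peak flags aligned to the 12-min step grid.

SPL of a segment is 10*log10(mean(p^2) / p_ref^2) in dB re 1 uPa
(p_ref = 1 uPa).  A segment is flagged as containing a boat pass when its
mean squared pressure is at least ``factor`` (default 1.8) times the basal
ambient level — on the linear mean-square scale this is a fixed dB offset
of 10*log10(factor) (~2.55 dB at 1.8).  A dB-multiplicative comparison
(SPL >= factor * basal_SPL) is available via ``scale="db"`` since the
original threshold scale is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import ConfigurationError

__all__ = [
    "DB_FLOOR",
    "Calibration",
    "AudioClip",
    "SplSeries",
    "NoisePeakSeries",
    "calibrate",
    "read_wav",
    "compute_spl",
    "spl_series",
    "compute_psd",
    "detect_noise_peaks",
    "estimate_basal",
    "align_noise_to_steps",
]

#: dB value reported for segments with zero mean squared pressure.
DB_FLOOR = -100.0

_INT16_FULL_SCALE = 32768.0


@dataclass(frozen=True)
class Calibration:
    """Hydrophone + recorder calibration chain.

    sensitivity_db is the hydrophone sensitivity in dB re 1 V/uPa (e.g.
    -170 for the deployed unit), gain_db the recorder gain, and
    full_scale_volts the voltage mapped to 16-bit full scale.
    """

    sensitivity_db: float
    gain_db: float = 0.0
    full_scale_volts: float = 1.0

    def __post_init__(self) -> None:
        vals = [self.sensitivity_db, self.gain_db, self.full_scale_volts]
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("calibration values must be finite")
        if self.full_scale_volts <= 0:
            raise ConfigurationError("full_scale_volts must be positive")

    @property
    def volts_per_upa(self) -> float:
        return 10.0 ** ((self.sensitivity_db + self.gain_db) / 20.0)


@dataclass
class AudioClip:
    """Calibrated pressure samples in uPa."""

    samples: np.ndarray
    rate: int = 44100
    start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.start is not None:
            self.start = pd.Timestamp(self.start)
            if self.start.tzinfo is None:
                self.start = self.start.tz_localize("UTC")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class SplSeries:
    """Per-second SPL values (dB re 1 uPa), trailing partial second dropped."""

    spl: np.ndarray
    segment_start_times: pd.DatetimeIndex | None = None
    floored: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.spl = np.asarray(self.spl, float)
        if self.floored is None:
            self.floored = np.zeros(self.spl.shape, bool)
        self.floored = np.asarray(self.floored, bool)
        if self.segment_start_times is not None and len(
            self.segment_start_times
        ) != len(self.spl):
            raise ValueError("one start time per segment required")

    def __len__(self) -> int:
        return len(self.spl)


@dataclass
class NoisePeakSeries:
    """Binary motorboat-noise presence per 12-min step."""

    flags: np.ndarray
    basal_spl: float
    threshold_factor: float = 1.8
    step_duration: float = 720.0
    origin: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, int)
        if not np.all(np.isin(self.flags, (0, 1))):
            raise ValueError("flags must be binary")
        if self.threshold_factor <= 1:
            raise ValueError("threshold_factor must exceed 1")


def calibrate(
    raw,
    sensitivity_db: float | None = None,
    gain_db: float = 0.0,
    full_scale_volts: float = 1.0,
    rate: int = 44100,
    start=None,
) -> AudioClip:
    """Convert raw 16-bit integer samples to calibrated pressure in uPa.

    pressure = raw / 32768 * full_scale_volts / 10**((sensitivity+gain)/20)

    There are no silent defaults for the sensitivity: omitting it raises a
    ConfigurationError.
    """
    if sensitivity_db is None:
        raise ConfigurationError("hydrophone sensitivity is required (no default)")
    cal = Calibration(sensitivity_db, gain_db, full_scale_volts)
    raw = np.asarray(raw)
    if raw.size and (raw.min() < -32768 or raw.max() > 32767):
        raise ValueError("raw samples outside the 16-bit integer range")
    volts = raw.astype(float) / _INT16_FULL_SCALE * cal.full_scale_volts
    pressure = volts / cal.volts_per_upa
    return AudioClip(samples=pressure, rate=rate, start=start)


def read_wav(path, calibration: Calibration, start=None) -> AudioClip:
    """Read a PCM16 WAV file and apply the calibration chain."""
    rate, raw = wavfile.read(path)
    if raw.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM WAV, got dtype {raw.dtype}")
    if raw.ndim > 1:
        raw = raw[:, 0]
    return calibrate(
        raw,
        sensitivity_db=calibration.sensitivity_db,
        gain_db=calibration.gain_db,
        full_scale_volts=calibration.full_scale_volts,
        rate=rate,
        start=start,
    )


def compute_spl(samples, floor_db: float = DB_FLOOR) -> float:
    """SPL of one segment: 10*log10(mean(p^2)) dB re 1 uPa.

    All-zero (or empty-mean) segments return the configured floor.
    """
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise ValueError("segment must be non-empty")
    msp = float(np.mean(samples**2))
    if msp <= 0.0:
        return float(floor_db)
    return float(10.0 * np.log10(msp))


def spl_series(clip: AudioClip, floor_db: float = DB_FLOOR) -> SplSeries:
    """Per-second SPL of a clip; the trailing partial segment is dropped."""
    n_seg = int(clip.duration)
    if n_seg < 1:
        raise ValueError("clip shorter than one second")
    segs = clip.samples[: n_seg * clip.rate].reshape(n_seg, clip.rate)
    msp = np.mean(segs**2, axis=1)
    floored = msp <= 0.0
    spl = np.where(floored, floor_db, 10.0 * np.log10(np.where(floored, 1.0, msp)))
    times = None
    if clip.start is not None:
        times = clip.start + pd.to_timedelta(np.arange(n_seg), unit="s")
    return SplSeries(spl=spl, segment_start_times=times, floored=floored)


def compute_psd(clip: AudioClip, floor_db: float = DB_FLOOR):
    """Power spectral density per 1-s non-overlapping segment.

    Returns ``(freqs, psd_db)`` with ``psd_db`` of shape (n_segments,
    n_freqs) in dB re 1 uPa^2/Hz over the full band (0 to Nyquist).
    Rectangular windowing keeps Parseval exact: the linear-scale PSD
    integrated over frequency equals the segment's mean squared pressure.
    """
    n_seg = int(clip.duration)
    if n_seg < 1:
        raise ValueError("clip shorter than one second")
    segs = clip.samples[: n_seg * clip.rate].reshape(n_seg, clip.rate)
    freqs, pxx = signal.periodogram(
        segs, fs=clip.rate, window="boxcar", detrend=False, scaling="density", axis=-1
    )
    floor_lin = 10.0 ** (floor_db / 10.0)
    psd_db = 10.0 * np.log10(np.maximum(pxx, floor_lin))
    return freqs, psd_db


def detect_noise_peaks(
    spl: SplSeries | np.ndarray,
    basal: float,
    factor: float = 1.8,
    scale: str = "linear",
) -> np.ndarray:
    """Flag segments whose level exceeds ``factor`` times the basal level.

    scale="linear" (default): mean squared pressure >= factor * basal mean
    squared pressure, i.e. SPL >= basal + 10*log10(factor) dB.
    scale="db": SPL >= factor * basal (dB-multiplicative comparison).
    Segments exactly at threshold are flagged.
    """
    if not np.isfinite(basal):
        raise ValueError("basal level must be finite")
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    values = spl.spl if isinstance(spl, SplSeries) else np.asarray(spl, float)
    if scale == "linear":
        threshold = basal + 10.0 * np.log10(factor)
    elif scale == "db":
        threshold = factor * basal
    else:
        raise ValueError(f"unknown threshold scale {scale!r}")
    return (values >= threshold).astype(int)


def estimate_basal(spl: SplSeries | np.ndarray, quantile: float = 0.25) -> float:
    """Estimate the basal ambient level as a robust low quantile of SPL.

    The default 0.25 quantile is the median of the quietest half of the
    segments, insensitive to boat passes occupying a minority of the
    record.  Requires at least 60 segments (one duty-cycled minute).
    """
    values = spl.spl if isinstance(spl, SplSeries) else np.asarray(spl, float)
    if values.size < 60:
        raise ValueError(f"need >= 60 segments to estimate basal, got {values.size}")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.quantile(values, quantile))


def align_noise_to_steps(
    flags,
    segment_start_times,
    origin,
    step_duration: float = 720.0,
    n_steps: int | None = None,
    basal_spl: float = np.nan,
    threshold_factor: float = 1.8,
) -> NoisePeakSeries:
    """Collapse per-second flags onto the step grid: a step is noisy iff any
    contained segment is flagged."""
    flags = np.asarray(flags, int)
    origin = pd.Timestamp(origin)
    if origin.tzinfo is None:
        origin = origin.tz_localize("UTC")
    times = pd.DatetimeIndex(segment_start_times)
    if times.tz is None:
        times = times.tz_localize("UTC")
    if len(times) != len(flags):
        raise ValueError("one start time per flag required")
    offsets = (times - origin).total_seconds()
    if np.any(np.asarray(offsets) < 0):
        raise ValueError("segment before the step-grid origin")
    steps = (np.asarray(offsets) // step_duration).astype(int)
    if n_steps is None:
        n_steps = int(steps.max()) + 1 if len(steps) else 0
    elif np.any(steps >= n_steps):
        raise ValueError("segment outside the step grid")
    step_flags = np.zeros(n_steps, int)
    np.maximum.at(step_flags, steps, flags)
    return NoisePeakSeries(
        flags=step_flags,
        basal_spl=float(basal_spl),
        threshold_factor=threshold_factor,
        step_duration=step_duration,
        origin=origin,
    )
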