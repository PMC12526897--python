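"""Acoustic feature extraction for pulsed fish calls.

Covers the measurement chain of a calibrated hydrophone recording:
voltage-to-pressure conversion through the receiving voltage sensitivity,
zero-to-peak sound pressure level (SPL_0-pk, dB re 1 uPa), pulse detection
with quality flags, inter-pulse intervals (IPI) grouped into trains, and
energy spectral density (ESD) with ensemble percentile summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .wavelets import Waveform


@dataclass(frozen=True)
class HydrophoneCal:
    """Hydrophone calibration: sensitivity in dB re 1 V/uPa, gain in dB."""

    sensitivity: float = -164.6
    gain: float = 0.0
    fs: float = 48000.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass(frozen=True)
class DetectionConfig:
    """Pulse-detection thresholds.

    ``min_height`` is a multiple of the noise MAD (median absolute
    deviation, scaled to the Gaussian sigma); pulses closer than
    ``min_separation`` are flagged as overlapping; a silence longer than
    ``train_gap`` starts a new train; samples at or above ``clip_level``
    of full scale flag the pulse as clipped.
    """

    min_height: float = 6.0
    min_separation: float = 10.0  # ms
    train_gap: float = 100.0  # ms
    clip_level: float = 0.99

    def __post_init__(self):
        if not self.min_separation < self.train_gap:
            raise ValueError("min_separation must be < train_gap")


@dataclass
class PulseCall:
    """One detected pulse with its calibrated level."""

    waveform: Waveform
    peak_index: int
    spl_0pk: float


@dataclass
class ESDSummary:
    """Ensemble ESD: percentile curves, per-bin density map, RMS level."""

    frequencies: np.ndarray
    percentile_curves: dict[int, np.ndarray]
    density_map: np.ndarray
    rms_level: float


# ---------------------------------------------------------------------------
# calibration and levels
# ---------------------------------------------------------------------------


def voltage_to_pressure(v: np.ndarray, cal: HydrophoneCal) -> np.ndarray:
    """Convert recorded volts to acoustic pressure in uPa.

    ``p = v * 10**(-(sensitivity + gain)/20)``; exactly invertible.
    """
    v = np.asarray(v, dtype=float)
    return v * 10.0 ** (-(cal.sensitivity + cal.gain) / 20.0)


def pressure_to_voltage(p: np.ndarray, cal: HydrophoneCal) -> np.ndarray:
    """Inverse of :func:`voltage_to_pressure`."""
    p = np.asarray(p, dtype=float)
    return p * 10.0 ** ((cal.sensitivity + cal.gain) / 20.0)


def compute_spl0pk(w: Waveform) -> float:
    """Zero-to-peak SPL in dB re 1 uPa: ``20 log10(max |p|)``."""
    peak = np.max(np.abs(w.samples))
    if peak == 0:
        raise ValueError("all-zero waveform has no defined SPL")
    return float(20.0 * np.log10(peak))


def scale_to_spl0pk(w: Waveform, spl_db: float) -> Waveform:
    """Rescale a waveform so its zero-to-peak SPL equals ``spl_db``."""
    peak = np.max(np.abs(w.samples))
    if peak == 0:
        raise ValueError("cannot scale an all-zero waveform")
    target_peak = 10.0 ** (spl_db / 20.0)
    return Waveform(w.samples * (target_peak / peak), w.fs, "uPa")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_pulses(w: Waveform, cfg: DetectionConfig | None = None):
    """Detect pulse peaks above a robust noise threshold.

    Returns ``(peaks, flags)``: sample indices of local maxima of ``|p|``
    exceeding ``min_height`` times the noise MAD (Gaussian-consistent),
    separated by at least ``min_separation``; ``flags`` maps each peak to
    the set of quality flags drawn from ``{"clipped", "overlapping"}``.
    """
    cfg = cfg or DetectionConfig()
    signed = np.asarray(w.samples, dtype=float)
    x = np.abs(signed)
    if len(x) == 0:
        return np.array([], dtype=int), []
    # robust noise scale: MAD of the signed record, Gaussian-consistent
    mad = np.median(np.abs(signed - np.median(signed))) * 1.4826
    threshold = cfg.min_height * mad if mad > 0 else cfg.min_height * 1e-12
    distance = max(1, int(round(cfg.min_separation * 1e-3 * w.fs)))
    peaks, _ = find_peaks(x, height=threshold, distance=distance)
    flags = []
    for i, p in enumerate(peaks):
        f = set()
        # clipping is judged against digital full scale, which only exists
        # for normalized recordings
        if w.unit == "normalized" and x[p] >= cfg.clip_level:
            f.add("clipped")
        gap = cfg.min_separation * 2e-3 * w.fs
        if i > 0 and p - peaks[i - 1] < gap:
            f.add("overlapping")
        if i + 1 < len(peaks) and peaks[i + 1] - p < gap:
            f.add("overlapping")
        flags.append(f)
    return peaks, flags


def extract_ipi(peaks: np.ndarray, fs: float,
                cfg: DetectionConfig | None = None) -> list[list[float]]:
    """Group peaks into trains and return per-train IPI lists in ms.

    Consecutive peak spacings beyond ``train_gap`` start a new train;
    single-pulse trains contribute an empty IPI list.
    """
    cfg = cfg or DetectionConfig()
    peaks = np.asarray(peaks)
    if len(peaks) == 0:
        return []
    gaps_ms = np.diff(peaks) / fs * 1e3
    trains: list[list[float]] = [[]]
    for g in gaps_ms:
        if g > cfg.train_gap:
            trains.append([])
        else:
            trains[-1].append(float(g))
    return trains


def train_sizes(trains: list[list[float]]) -> list[int]:
    """Pulse count per train (IPI count + 1)."""
    return [len(t) + 1 for t in trains]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def esd(w: Waveform) -> tuple[np.ndarray, np.ndarray]:
    """One-sided energy spectral density.

    Returns ``(frequencies, esd)`` with ESD in dB re 1 uPa^2 s/Hz (or the
    squared unit of the input): ``2 |X(f) dt|^2`` for positive frequencies,
    satisfying Parseval's identity ``sum(ESD) df == sum(p^2) dt``.
    """
    x = np.asarray(w.samples, dtype=float)
    if not np.any(x):
        raise ValueError("all-zero waveform has no defined ESD")
    n = len(x)
    dt = 1.0 / w.fs
    X = np.fft.rfft(x) * dt
    e = np.abs(X) ** 2
    e[1:] *= 2.0
    if n % 2 == 0 and len(e) > 1:
        e[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, dt)
    return freqs, e


def esd_db(w: Waveform, floor: float = 1e-300):
    freqs, e = esd(w)
    return freqs, 10.0 * np.log10(np.maximum(e, floor))


def esd_peak_frequency(w: Waveform) -> float:
    """Frequency (Hz) at which the ESD attains its maximum."""
    freqs, e = esd(w)
    return float(freqs[np.argmax(e)])


def esd_percentiles(calls: list[Waveform],
                    percents: tuple[int, ...] = (1, 5, 50, 95, 99),
                    density_bins: int = 30) -> ESDSummary:
    """Per-frequency-bin empirical percentiles of ESD across an ensemble.

    All calls must share length and sampling rate.  The density map is a
    per-frequency histogram of dB levels, each frequency column normalized
    to sum to 1.
    """
    if len(calls) < 2:
        raise ValueError("need at least two calls")
    n = len(calls[0].samples)
    fs = calls[0].fs
    for c in calls[1:]:
        if len(c.samples) != n or c.fs != fs:
            raise ValueError("all calls must share length and fs")
    spectra = []
    for c in calls:
        freqs, e = esd_db(c)
        spectra.append(e)
    S = np.array(spectra)  # (n_calls, n_bins)
    curves = {p: np.percentile(S, p, axis=0) for p in percents}
    lo, hi = S.min(), S.max()
    edges = np.linspace(lo, hi + 1e-9, density_bins + 1)
    density = np.zeros((density_bins, S.shape[1]))
    for j in range(S.shape[1]):
        counts, _ = np.histogram(S[:, j], bins=edges)
        density[:, j] = counts / counts.sum()
    rms = float(np.sqrt(np.mean([np.mean(c.samples ** 2) for c in calls])))
    rms_level = 20.0 * np.log10(rms) if rms > 0 else -np.inf
    return ESDSummary(freqs, curves, density, rms_level)
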