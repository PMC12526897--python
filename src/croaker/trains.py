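"""Pulse-train assembly, quartile-matched variability models and SNR noise.

Multipulse croaker calls are assembled by overlap-adding single-pulse
syntheses at inter-pulse intervals (IPI) drawn from a quartile-matched
distribution, with per-pulse zero-to-peak SPL targets drawn likewise.
The distribution models are fitted from printed quartile summaries alone:

* lognormal — ``mu = ln(median)``, ``sigma = ln(q3/q1) / (2 * 0.6745)``
  (0.6745 is the standard normal quartile), natural for the positive,
  nearly log-symmetric IPI;
* normal — ``mean = median``, ``sd = (q3 - q1) / 1.349``, natural for
  SPL values already expressed in dB.

Both models reproduce their input quartiles exactly.  White Gaussian noise
at a prescribed SNR emulates degraded recordings; the SNR can be defined
over the pulse-active window or the full record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import compute_spl0pk, scale_to_spl0pk
from .wavelets import Waveform

_Q = 0.6744897501960817  # standard normal upper quartile


@dataclass(frozen=True)
class QuartileModel:
    """Distribution fitted to (q1, median, q3) by quantile matching."""

    family: str  # "lognormal" | "normal"
    q1: float
    median: float
    q3: float
    loc: float  # mu (lognormal) or mean (normal)
    scale: float  # sigma (log-domain) or sd

    @classmethod
    def fit(cls, q1: float, median: float, q3: float,
            family: str = "lognormal") -> "QuartileModel":
        if not q1 < median < q3:
            raise ValueError("need q1 < median < q3")
        if family == "lognormal":
            if q1 <= 0:
                raise ValueError("lognormal requires positive quartiles")
            loc = float(np.log(median))
            scale = float(np.log(q3 / q1) / (2 * _Q))
        elif family == "normal":
            loc = float(median)
            scale = float((q3 - q1) / (2 * _Q))
        else:
            raise ValueError(f"unknown family {family!r}; use 'lognormal' "
                             "or 'normal'")
        return cls(family, q1, median, q3, loc, scale)

    def quantile(self, p: float) -> float:
        from scipy.stats import norm

        z = norm.ppf(p)
        if self.family == "lognormal":
            return float(np.exp(self.loc + self.scale * z))
        return float(self.loc + self.scale * z)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(n)
        if self.family == "lognormal":
            return np.exp(self.loc + self.scale * z)
        return self.loc + self.scale * z


def fit_quartile_model(q1: float, median: float, q3: float,
                       family: str = "lognormal") -> QuartileModel:
    """Functional alias of :meth:`QuartileModel.fit`."""
    return QuartileModel.fit(q1, median, q3, family)


#: Printed quartiles of the measured single-pulse SPL_0-pk (dB re 1 uPa).
SPL_QUARTILES = (154.30, 154.99, 156.06)
#: Printed quartiles of the measured inter-pulse interval (ms).
IPI_QUARTILES = (19.75, 20.95, 22.21)


def default_spl_model() -> QuartileModel:
    return QuartileModel.fit(*SPL_QUARTILES, family="normal")


def default_ipi_model() -> QuartileModel:
    return QuartileModel.fit(*IPI_QUARTILES, family="lognormal")


# ---------------------------------------------------------------------------
# train assembly
# ---------------------------------------------------------------------------


@dataclass
class PulseTrain:
    """Assembled multipulse call with its generating parameters."""

    pulses: list[Waveform]
    ipis: list[float]  # ms, length = len(pulses) - 1
    spl_per_pulse: list[float]  # dB re 1 uPa
    assembled: Waveform

    @property
    def chain(self) -> int:
        return len(self.pulses)


def assemble_train(pulse, ipis, spl_targets, fs: float = 48000.0,
                   tail_samples: int | None = None) -> PulseTrain:
    """Overlap-add single pulses at prescribed IPIs and SPL targets.

    Parameters
    ----------
    pulse : Waveform or list of Waveform
        The pulse synthesis to repeat, or one waveform per pulse.
    ipis : list of float
        Peak-to-peak intervals in ms; ``len(spl_targets) == len(ipis) + 1``.
    spl_targets : list of float
        Per-pulse zero-to-peak SPL in dB re 1 uPa.
    """
    n_pulses = len(spl_targets)
    if len(ipis) != n_pulses - 1:
        raise ValueError("need len(spl_targets) == len(ipis) + 1")
    if isinstance(pulse, Waveform):
        pulses_in = [pulse] * n_pulses
    else:
        pulses_in = list(pulse)
        if len(pulses_in) != n_pulses:
            raise ValueError("need one pulse per SPL target")
    scaled = [scale_to_spl0pk(p, s) for p, s in zip(pulses_in, spl_targets)]
    peak_offsets = [int(np.argmax(np.abs(p.samples))) for p in scaled]
    spacing = [int(round(i * 1e-3 * fs)) for i in ipis]
    min_spacing = min(spacing) if spacing else None

    def _active_extent(x):
        nz = np.flatnonzero(np.abs(x) > 1e-12 * np.max(np.abs(x)))
        return int(nz[-1] - nz[0] + 1) if nz.size else 0

    support = max(_active_extent(p.samples) for p in scaled)
    if min_spacing is not None and min_spacing < support:
        import logging

        logging.getLogger(__name__).warning(
            "IPI spacing %d samples is shorter than the pulse support %d; "
            "pulses will overlap", min_spacing, support)

    peak_positions = np.concatenate([[0], np.cumsum(spacing)]).astype(int)
    tail = tail_samples if tail_samples is not None else support
    starts = [pp - po for pp, po in zip(peak_positions, peak_offsets)]
    shift = -min(min(starts), 0)
    total = max(s + shift + len(p.samples)
                for s, p in zip(starts, scaled)) + tail
    out = np.zeros(total)
    for s, p in zip(starts, scaled):
        out[s + shift:s + shift + len(p.samples)] += p.samples
    return PulseTrain(scaled, [float(i) for i in ipis],
                      [float(s) for s in spl_targets],
                      Waveform(out, fs, "uPa"))


def draw_train(pulse: Waveform, n_pulses: int, ipi_model: QuartileModel,
               spl_model: QuartileModel,
               rng: np.random.Generator) -> PulseTrain:
    """Assemble a train with model-drawn IPIs and per-pulse SPL targets."""
    ipis = list(ipi_model.sample(n_pulses - 1, rng)) if n_pulses > 1 else []
    spls = list(spl_model.sample(n_pulses, rng))
    return assemble_train(pulse, ipis, spls, fs=pulse.fs)


# ---------------------------------------------------------------------------
# noise degradation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Target SNR in dB for white Gaussian degradation.

    ``power_window`` selects the signal-power reference: ``"pulse_active"``
    uses samples whose magnitude exceeds 1% of the peak (silence between
    pulses does not dilute the signal power), ``"full"`` uses every sample.
    """

    snr_db: float
    kind: str = "white_gaussian"
    power_window: str = "pulse_active"
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.kind != "white_gaussian":
            raise ValueError("only white_gaussian noise is supported")
        if self.power_window not in ("pulse_active", "full"):
            raise ValueError("power_window must be 'pulse_active' or 'full'")


def _active_mask(x: np.ndarray, rel: float = 0.01) -> np.ndarray:
    m = np.abs(x) > rel * np.max(np.abs(x))
    return m if m.any() else np.ones_like(m, dtype=bool)


def add_noise_at_snr(clean: Waveform, spec: NoiseSpec,
                     rng: np.random.Generator | None = None) -> Waveform:
    """Add white Gaussian noise so that ``10 log10(Ps/Pn) == snr_db``."""
    x = np.asarray(clean.samples, dtype=float)
    if not np.any(x):
        raise ValueError("clean waveform has zero power")
    mask = (_active_mask(x) if spec.power_window == "pulse_active"
            else np.ones(len(x), dtype=bool))
    p_signal = float(np.mean(x[mask] ** 2))
    p_noise = p_signal / 10.0 ** (spec.snr_db / 10.0)
    rng = rng or np.random.default_rng(spec.seed)
    noise = rng.standard_normal(len(x)) * np.sqrt(p_noise)
    return Waveform(x + noise, clean.fs, clean.unit)


def measure_snr(clean: Waveform, noisy: Waveform,
                power_window: str = "pulse_active") -> float:
    """SNR in dB of ``noisy`` relative to ``clean`` over a power window.

    Returns ``inf`` for identical signals.
    """
    x = np.asarray(clean.samples, dtype=float)
    y = np.asarray(noisy.samples, dtype=float)
    if x.shape != y.shape:
        raise ValueError("waveforms must have equal length")
    resid = y - x
    mask = (_active_mask(x) if power_window == "pulse_active"
            else np.ones(len(x), dtype=bool))
    p_signal = float(np.mean(x[mask] ** 2))
    p_noise = float(np.mean(resid[mask] ** 2))
    if p_noise == 0:
        return float("inf")
    return float(10.0 * np.log10(p_signal / p_noise))
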