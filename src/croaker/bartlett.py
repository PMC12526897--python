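"""Normalized Bartlett-processor sensitivity analysis.

The Bartlett processor scores the spectral similarity between a reference
call and a perturbed synthesis.  With band-limited, unit-norm magnitude
spectra ``R_ref`` and ``R_cand`` and the trace-normalized cross-spectral
matrix ``C = R_ref R_ref^T`` built from the reference, the single-snapshot
power is

    B = R_cand^T C R_cand / (R_cand^T R_cand) = |<R_ref, R_cand>|^2,

i.e. the squared cosine between the two spectra: 1 at a perfect match,
0 for disjoint spectral support, and invariant to positive rescaling of
either waveform.  For ``L > 1`` snapshots, ``C`` averages the outer
products of the snapshot spectra and ``B`` is the quadratic form in the
candidate spectrum.

Because magnitude spectra are used, a rigid time shift of the whole call
leaves ``B`` unchanged; sensitivity to the delay parameters arises through
the interference pattern between components, which magnitude spectra do
capture.

Sweeping one parameter of an optimal synthesis specification over its
search range, with all other parameters held at their optima, yields a
sensitivity curve whose ``B >= threshold`` interval around the optimum is
the parameter's valid modeling range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import SearchBounds
from .wavelets import (
    MotherWavelet,
    SynthesisSpec,
    Waveform,
    build_mother_wavelet,
    synthesize_call,
)

FIELDS = ("amplitude", "delay", "length")


@dataclass(frozen=True)
class SensitivityConfig:
    """Sweep settings: grid resolution, similarity threshold, analysis band."""

    grid_points: int = 201
    threshold: float = 0.98
    band: tuple[float, float] = (50.0, 5000.0)
    snapshots: int = 1

    def validate(self) -> None:
        if self.grid_points < 3:
            raise ValueError("grid_points must be >= 3")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if not 0 <= self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 <= lo < hi")


@dataclass
class NormalizedSpectrum:
    """Unit-norm band-limited magnitude spectrum."""

    frequencies: np.ndarray
    values: np.ndarray

    @classmethod
    def from_waveform(cls, w: Waveform,
                      band: tuple[float, float] = (50.0, 5000.0)
                      ) -> "NormalizedSpectrum":
        x = np.asarray(w.samples, dtype=float)
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), 1.0 / w.fs)
        sel = (freqs >= band[0]) & (freqs <= band[1])
        v = spec[sel]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("waveform has zero energy in the analysis band")
        return cls(freqs[sel], v / norm)


@dataclass
class CrossSpectralMatrix:
    """Trace-normalized average of snapshot outer products (Hermitian)."""

    matrix: np.ndarray

    @classmethod
    def from_snapshots(cls, spectra: list[NormalizedSpectrum]
                       ) -> "CrossSpectralMatrix":
        if not spectra:
            raise ValueError("need at least one snapshot")
        C = sum(np.outer(s.values, s.values) for s in spectra)
        C = C / np.trace(C)
        return cls(C)

    def power(self, candidate: NormalizedSpectrum) -> float:
        v = candidate.values
        return float(v @ self.matrix @ v / (v @ v))


@dataclass
class SensitivityCurve:
    """Bartlett similarity versus one swept parameter."""

    parameter_id: tuple[int, str]  # (component index, field name)
    grid: np.ndarray
    similarity: np.ndarray
    optimum: float
    valid_interval: tuple[float, float]

    @property
    def interval_width(self) -> float:
        lo, hi = self.valid_interval
        return hi - lo


def bartlett_power(reference: Waveform, candidate: Waveform,
                   config: SensitivityConfig | None = None) -> float:
    """Normalized Bartlett similarity of two waveforms (band-limited)."""
    config = config or SensitivityConfig()
    config.validate()
    if reference.fs != candidate.fs:
        raise ValueError("waveforms must share the sampling rate")
    ref = NormalizedSpectrum.from_waveform(reference, config.band)
    cand = NormalizedSpectrum.from_waveform(candidate, config.band)
    if len(ref.values) != len(cand.values):
        raise ValueError("waveforms must have equal length")
    # single-snapshot case reduces to the squared spectral cosine
    return float((ref.values @ cand.values) ** 2)


def bartlett_power_multi(snapshots: list[Waveform], candidate: Waveform,
                         config: SensitivityConfig | None = None) -> float:
    """Multi-snapshot Bartlett power using the averaged cross-spectral matrix."""
    config = config or SensitivityConfig()
    specs = [NormalizedSpectrum.from_waveform(s, config.band)
             for s in snapshots]
    C = CrossSpectralMatrix.from_snapshots(specs)
    return C.power(NormalizedSpectrum.from_waveform(candidate, config.band))


def sweep_parameter(spec: SynthesisSpec, component_index: int, fieldname: str,
                    bounds: SearchBounds, reference: Waveform,
                    config: SensitivityConfig | None = None,
                    mother: MotherWavelet | None = None) -> SensitivityCurve:
    """Sweep one parameter over its search range, others held at ``spec``.

    The grid spans the field's search-space interval and always contains
    the spec's current (optimal) value exactly, so the curve's peak is
    evaluated rather than interpolated.
    """
    config = config or SensitivityConfig()
    config.validate()
    mother = mother or build_mother_wavelet()
    if not 0 <= component_index < len(spec.components):
        raise IndexError(
            f"component_index {component_index} out of range "
            f"(spec has {len(spec.components)} components)")
    if fieldname not in FIELDS:
        raise ValueError(f"field must be one of {FIELDS}, got {fieldname!r}")
    lo, hi = getattr(bounds, fieldname)
    optimum = getattr(spec.components[component_index], fieldname)
    grid = np.linspace(lo, hi, config.grid_points)
    grid = np.unique(np.append(grid, optimum))
    sims = np.empty(len(grid))
    work = SynthesisSpec.from_dict(spec.to_dict())
    for i, val in enumerate(grid):
        setattr(work.components[component_index], fieldname, float(val))
        cand = synthesize_call(work, mother)
        sims[i] = bartlett_power(reference, cand, config)
    curve = SensitivityCurve((component_index, fieldname), grid, sims,
                             optimum, (np.nan, np.nan))
    curve.valid_interval = valid_interval(curve, config.threshold)
    return curve


def valid_interval(curve: SensitivityCurve,
                   threshold: float) -> tuple[float, float]:
    """Maximal contiguous interval around the optimum with ``B >= threshold``.

    Endpoints are linearly interpolated between grid points where the
    curve crosses the threshold.
    """
    grid, sims = curve.grid, curve.similarity
    i0 = int(np.argmin(np.abs(grid - curve.optimum)))
    if sims[i0] < threshold:
        raise ValueError(
            f"similarity at the optimum ({sims[i0]:.4f}) is below the "
            f"threshold {threshold}; inconsistent curve")

    def cross(i, j):
        """Interpolate the threshold crossing between grid points i, j."""
        s0, s1 = sims[i], sims[j]
        if s1 == s0:
            return grid[j]
        t = (threshold - s0) / (s1 - s0)
        return float(grid[i] + t * (grid[j] - grid[i]))

    lo = grid[0]
    for i in range(i0, 0, -1):
        if sims[i - 1] < threshold:
            lo = cross(i, i - 1)
            break
    hi = grid[-1]
    for i in range(i0, len(grid) - 1):
        if sims[i + 1] < threshold:
            hi = cross(i, i + 1)
            break
    return (float(lo), float(hi))


def sweep_all(spec: SynthesisSpec, bounds: SearchBounds, reference: Waveform,
              config: SensitivityConfig | None = None,
              mother: MotherWavelet | None = None) -> list[SensitivityCurve]:
    """Sensitivity curves for every (component, field) pair of ``spec``."""
    mother = mother or build_mother_wavelet()
    curves = []
    for ci in range(len(spec.components)):
        for fieldname in FIELDS:
            curves.append(sweep_parameter(spec, ci, fieldname, bounds,
                                          reference, config, mother))
    return curves


def curves_frame(curves: list[SensitivityCurve]):
    """Long-format DataFrame of sweep curves (component, field, grid, B)."""
    import pandas as pd

    rows = []
    for c in curves:
        ci, fieldname = c.parameter_id
        for g, s in zip(c.grid, c.similarity):
            rows.append((ci, fieldname, g, s))
    return pd.DataFrame(rows, columns=["component", "field", "grid_value",
                                       "bartlett_power"])


def intervals_frame(curves: list[SensitivityCurve]):
    """One row per swept parameter with its valid interval."""
    import pandas as pd

    rows = []
    for c in curves:
        ci, fieldname = c.parameter_id
        rows.append((ci, fieldname, c.optimum, *c.valid_interval,
                     c.interval_width))
    return pd.DataFrame(rows, columns=["component", "field", "optimum",
                                       "lo", "hi", "width"])
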