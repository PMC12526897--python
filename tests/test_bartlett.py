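"""Normalized Bartlett processor and parameter sensitivity sweeps."""

import numpy as np
import pytest

import croaker as ck
from croaker.bartlett import (
    SensitivityConfig,
    SensitivityCurve,
    bartlett_power_multi,
    valid_interval,
)
from croaker.inversion import SearchBounds


def _tone(freq, fs=48000.0, n=1536):
    t = np.arange(n) / fs
    return ck.Waveform(np.sin(2 * np.pi * freq * t), fs)


class TestBartlettPower:
    def test_self_match_is_one(self, reference_call):
        assert ck.bartlett_power(reference_call, reference_call) == \
            pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, reference_call):
        scaled = ck.Waveform(0.37 * reference_call.samples,
                             reference_call.fs)
        assert ck.bartlett_power(reference_call, scaled) == \
            pytest.approx(1.0, abs=1e-12)

    def test_disjoint_spectra_give_zero(self):
        # bin-centered tones occupy single disjoint FFT bins
        a = _tone(500.0)   # 16 * 31.25 Hz
        b = _tone(1000.0)  # 32 * 31.25 Hz
        assert ck.bartlett_power(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_single_snapshot(self, reference_call, rng):
        other = ck.Waveform(
            reference_call.samples + 0.1 * rng.standard_normal(1536),
            reference_call.fs)
        assert ck.bartlett_power(reference_call, other) == \
            pytest.approx(ck.bartlett_power(other, reference_call))

    def test_bounded_in_unit_interval(self, reference_call, rng):
        for _ in range(10):
            cand = ck.Waveform(rng.standard_normal(1536),
                               reference_call.fs)
            b = ck.bartlett_power(reference_call, cand)
            assert 0.0 <= b <= 1.0 + 1e-12

    def test_multi_snapshot_reduces_to_single(self, reference_call):
        b1 = ck.bartlett_power(reference_call, reference_call)
        bm = bartlett_power_multi([reference_call], reference_call)
        assert b1 == pytest.approx(bm)

    def test_zero_band_energy_rejected(self):
        silent = ck.Waveform(np.zeros(1536), 48000.0)
        with pytest.raises(ValueError):
            ck.bartlett_power(silent, silent)

    def test_fs_mismatch_rejected(self, reference_call):
        other = ck.Waveform(reference_call.samples, 44100.0)
        with pytest.raises(ValueError):
            ck.bartlett_power(reference_call, other)


@pytest.fixture(scope="module")
def sweep_cfg():
    return SensitivityConfig(grid_points=61)


class TestSweep:
    def test_optimum_self_match(self, mother, reference_spec,
                                reference_call, sweep_cfg):
        """B at the spec's own amplitude value equals 1."""
        curve = ck.sweep_parameter(reference_spec, 1, "amplitude",
                                   SearchBounds(), reference_call,
                                   sweep_cfg, mother)
        i = int(np.argmin(np.abs(curve.grid - 0.52)))
        assert curve.grid[i] == pytest.approx(0.52)
        assert curve.similarity[i] == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_interval_finite_and_interior(self, mother,
                                                    reference_spec,
                                                    reference_call,
                                                    sweep_cfg):
        curve = ck.sweep_parameter(reference_spec, 1, "amplitude",
                                   SearchBounds(), reference_call,
                                   sweep_cfg, mother)
        lo, hi = curve.valid_interval
        assert 0.0 < lo < 0.52 < hi < 1.0

    def test_delay_narrower_than_amplitude_everywhere(
            self, mother, reference_spec, reference_call, sweep_cfg):
        """Delay is the more sensitive parameter for every component:
        its relative valid interval is narrower than amplitude's."""
        bounds = SearchBounds()
        for ci in range(5):
            widths = {}
            for fieldname in ("amplitude", "delay"):
                curve = ck.sweep_parameter(reference_spec, ci, fieldname,
                                           bounds, reference_call,
                                           sweep_cfg, mother)
                span = np.ptp(getattr(bounds, fieldname))
                widths[fieldname] = curve.interval_width / span
            assert widths["delay"] < widths["amplitude"]

    def test_interval_contains_optimum_for_all_parameters(
            self, mother, reference_spec, reference_call, sweep_cfg):
        curves = ck.sweep_all(reference_spec, SearchBounds(),
                              reference_call, sweep_cfg, mother)
        assert len(curves) == 15
        for c in curves:
            lo, hi = c.valid_interval
            assert lo <= c.optimum <= hi

    def test_monotone_nesting_with_threshold(self, mother, reference_spec,
                                             reference_call, sweep_cfg):
        curve = ck.sweep_parameter(reference_spec, 0, "length",
                                   SearchBounds(), reference_call,
                                   sweep_cfg, mother)
        lo95, hi95 = valid_interval(curve, 0.95)
        lo98, hi98 = valid_interval(curve, 0.98)
        lo99, hi99 = valid_interval(curve, 0.99)
        assert lo95 <= lo98 <= lo99 and hi99 <= hi98 <= hi95

    def test_out_of_range_component_rejected(self, mother, reference_spec,
                                             reference_call):
        with pytest.raises(IndexError):
            ck.sweep_parameter(reference_spec, 7, "delay", SearchBounds(),
                               reference_call, mother=mother)


class TestValidInterval:
    def test_identically_one_returns_full_range(self):
        grid = np.linspace(0, 1, 11)
        curve = SensitivityCurve((0, "amplitude"), grid, np.ones(11), 0.5,
                                 (np.nan, np.nan))
        assert valid_interval(curve, 0.98) == (0.0, 1.0)

    def test_three_point_interpolation(self):
        """1.0 at the center, 0.9 at the neighbors: crossing at the point
        where the linear segment reaches the threshold."""
        grid = np.array([0.0, 0.5, 1.0])
        sims = np.array([0.9, 1.0, 0.9])
        curve = SensitivityCurve((0, "delay"), grid, sims, 0.5,
                                 (np.nan, np.nan))
        lo, hi = valid_interval(curve, 0.98)
        # threshold sits 0.02 below the peak on a 0.10 drop over a 0.5-wide
        # grid gap: crossings at 0.5 -/+ 0.2 * 0.5
        assert lo == pytest.approx(0.4)
        assert hi == pytest.approx(0.6)

    def test_optimum_below_threshold_rejected(self):
        grid = np.linspace(0, 1, 5)
        curve = SensitivityCurve((0, "delay"), grid, np.full(5, 0.5), 0.5,
                                 (np.nan, np.nan))
        with pytest.raises(ValueError, match="below the threshold"):
            valid_interval(curve, 0.98)
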