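"""Composite objective and particle-swarm mechanics."""

import numpy as np
import pytest

import croaker as ck
from croaker.inversion import (
    PSOConfig,
    SearchBounds,
    init_swarm,
    minimize_pso,
    pso_update,
)


def _wave(x, fs=48000.0):
    return ck.Waveform(np.asarray(x, float), fs)


class TestCompositeObjective:
    def test_perfect_match_is_zero(self, rng):
        t = rng.standard_normal(256)
        assert ck.composite_objective(_wave(t), _wave(t)) == pytest.approx(0)

    def test_sign_flip_closed_form(self, rng):
        """candidate = -target: r = -1 and NMSE = 4, so J = 6."""
        t = rng.standard_normal(256)
        t -= t.mean()
        assert ck.composite_objective(_wave(t), _wave(-t)) == \
            pytest.approx(6.0)

    def test_half_amplitude_closed_form(self, rng):
        t = rng.standard_normal(256)
        t -= t.mean()
        assert ck.composite_objective(_wave(t), _wave(0.5 * t)) == \
            pytest.approx(0.25)

    def test_zero_energy_target_rejected(self):
        with pytest.raises(ValueError, match="zero-energy"):
            ck.composite_objective(_wave(np.zeros(64)), _wave(np.ones(64)))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ck.composite_objective(_wave(rng.standard_normal(64)),
                                   _wave(rng.standard_normal(65)))


def _sphere(X):
    return (np.atleast_2d(X) ** 2).sum(axis=1)


class TestSwarmMechanics:
    def test_degenerate_update_is_pure_drift(self):
        """c1 = c2 = 0, inertia 1: velocities unchanged, x <- x + v."""
        cfg = PSOConfig(population=8, max_iterations=5, c1=0.0, c2=0.0,
                        inertia=1.0, velocity_clamp_fraction=1.0,
                        velocity_clamp_final=1.0, n_components=1, seed=0)
        # bounds far wider than the step so no particle reflects
        lo, hi = np.full(3, -1000.0), np.full(3, 1000.0)
        state = init_swarm(_sphere, cfg, lo, hi)
        state.velocities[:] = 0.25
        x0 = state.positions.copy()
        pso_update(state, _sphere, cfg, lo, hi)
        assert np.allclose(state.positions, x0 + 0.25)
        assert np.allclose(state.velocities, 0.25)

    def test_particle_at_global_best_stays_fixed(self):
        cfg = PSOConfig(population=4, max_iterations=3, n_components=1,
                        seed=1)
        lo, hi = np.full(3, -1.0), np.full(3, 1.0)
        state = init_swarm(_sphere, cfg, lo, hi)
        gi = int(np.argmin(state.personal_best_scores))
        state.positions[gi] = state.global_best.copy()
        state.velocities[gi] = 0.0
        before = state.positions[gi].copy()
        pso_update(state, _sphere, cfg, lo, hi)
        assert np.allclose(state.positions[gi], before)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_sphere_oracle(self, seed):
        """Standard sanity oracle: 3-D sphere solved to < 1e-3."""
        cfg = PSOConfig(population=100, max_iterations=80, n_components=1,
                        seed=seed)
        lo, hi = np.full(3, -5.0), np.full(3, 5.0)
        _, best, history, _ = minimize_pso(_sphere, cfg, lo, hi)
        assert best < 1e-3
        assert np.all(np.diff(history) <= 1e-15)  # monotone global best

    def test_nonfinite_objective_demoted_to_inf(self):
        def nasty(X):
            f = _sphere(X)
            f[0] = np.nan
            return f

        cfg = PSOConfig(population=6, max_iterations=2, n_components=1,
                        seed=0)
        lo, hi = np.full(3, -1.0), np.full(3, 1.0)
        state = init_swarm(nasty, cfg, lo, hi)
        pso_update(state, nasty, cfg, lo, hi)
        assert np.isfinite(state.global_best_score)

    def test_infeasible_bounds_rejected(self):
        cfg = PSOConfig(population=4, max_iterations=2, n_components=1)
        with pytest.raises(ValueError, match="infeasible"):
            minimize_pso(_sphere, cfg, np.array([1.0] * 3),
                         np.array([0.0] * 3))


class TestWaveletInversion:
    def test_zero_target_rejected(self, mother):
        with pytest.raises(ValueError, match="zero-energy"):
            ck.WaveletInversion(_wave(np.zeros(1536)), mother=mother)

    def test_seed_determinism(self, mother, reference_call):
        cfg = PSOConfig(population=40, max_iterations=8, seed=9)
        model = ck.WaveletInversion(reference_call, mother=mother,
                                    config=cfg)
        a, b = model.fit(), model.fit()
        assert np.array_equal(a.best_spec.as_vector(),
                              b.best_spec.as_vector())
        assert np.array_equal(a.objective_history, b.objective_history)

    def test_components_sorted_by_delay(self, mother, reference_call):
        cfg = PSOConfig(population=30, max_iterations=5, seed=2)
        res = ck.WaveletInversion(reference_call, mother=mother,
                                  config=cfg).fit()
        delays = [c.delay for c in res.best_spec.components]
        assert delays == sorted(delays)

    def test_metrics_recomputed_from_spec(self, mother, reference_call):
        cfg = PSOConfig(population=30, max_iterations=5, seed=3)
        res = ck.WaveletInversion(reference_call, mother=mother,
                                  config=cfg).fit()
        recon = ck.synthesize_call(res.best_spec, mother)
        r = np.corrcoef(reference_call.samples, recon.samples)[0, 1]
        assert res.final_correlation == pytest.approx(r, abs=1e-12)

    def test_single_component_recovery_beats_grid_oracle(self, mother):
        """Brute-force grid oracle on (A, tau, sigma) confirms the swarm
        finds the global optimum of a one-component problem."""
        truth = ck.WaveletComponent(0.5, 10, 300)
        target = ck.render_component(truth, mother)
        cfg = PSOConfig(population=200, max_iterations=80, n_components=1,
                        seed=4)
        model = ck.WaveletInversion(target, mother=mother, config=cfg)
        res = model.fit()

        grid_best = np.inf
        t = model.target.samples
        for a in np.linspace(0.1, 1.0, 10):
            for tau in np.arange(-100, 101, 20):
                for sig in np.arange(20, 1001, 35):
                    cand = ck.render_component(
                        ck.WaveletComponent(a, tau, sig), mother)
                    J = ck.composite_objective(model.target, cand)
                    grid_best = min(grid_best, J)
        assert res.final_objective <= grid_best + 1e-12
        assert res.final_objective < 1e-3
        got = res.best_spec.components[0]
        # recovered timing/scale within the Bartlett-0.98 valid range
        curve_d = ck.sweep_parameter(
            ck.SynthesisSpec([truth]), 0, "delay", SearchBounds(), target,
            mother=mother)
        curve_s = ck.sweep_parameter(
            ck.SynthesisSpec([truth]), 0, "length", SearchBounds(), target,
            mother=mother)
        assert curve_d.valid_interval[0] <= got.delay <= \
            curve_d.valid_interval[1]
        assert curve_s.valid_interval[0] <= got.length <= \
            curve_s.valid_interval[1]

    @pytest.mark.parametrize("strategy", ["greedy", "hybrid"])
    def test_alternative_strategies_run(self, mother, reference_call,
                                        strategy):
        cfg = PSOConfig(population=60, max_iterations=10, seed=5)
        res = ck.WaveletInversion(reference_call, mother=mother, config=cfg,
                                  strategy=strategy).fit()
        assert len(res.best_spec.components) == 5
        assert np.isfinite(res.final_objective)

    def test_unknown_strategy_rejected(self, mother, reference_call):
        with pytest.raises(ValueError, match="strategy"):
            ck.WaveletInversion(reference_call, mother=mother,
                                strategy="annealing")

    def test_summary_contains_metrics(self, mother, reference_call):
        cfg = PSOConfig(population=20, max_iterations=3, seed=6)
        res = ck.WaveletInversion(reference_call, mother=mother,
                                  config=cfg).fit()
        s = res.summary()
        assert "correlation" in s and "RMSE" in s
        assert res.trajectories_frame().shape[0] == \
            len(res.objective_history) * 5
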