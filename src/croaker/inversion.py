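"""Particle-swarm inversion of wavelet parameters against a target call.

The model is the linear wavelet synthesis of :mod:`croaker.wavelets`; the
estimation problem is to find the ``3N`` parameters (amplitude, delay,
length per component) whose synthesis best reproduces a measured or target
waveform.  The discrepancy is a composite of waveform correlation and
normalized mean squared error,

    J = w1 * (1 - r) + w2 * NMSE,

minimized by a constricted particle swarm: each particle's velocity is
pulled toward its personal best and the swarm's global best position with
uniformly random per-dimension gains, clamped, and positions reflect off
the box constraints of the search space.

The public surface follows the model/results idiom: build a
:class:`WaveletInversion` from a target :class:`~croaker.wavelets.Waveform`
and call :meth:`~WaveletInversion.fit`, which returns
:class:`InversionResults` carrying the best specification, convergence
history, parameter trajectories and recomputed fit metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .wavelets import (
    MotherWavelet,
    SynthesisSpec,
    Waveform,
    build_mother_wavelet,
    synthesize_call,
    synthesize_positions,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchBounds:
    """Box constraints of the parameter search space (per component)."""

    amplitude: tuple[float, float] = (0.0, 1.0)
    delay: tuple[float, float] = (-100.0, 100.0)
    length: tuple[float, float] = (10.0, 1000.0)

    def validate(self) -> None:
        for name in ("amplitude", "delay", "length"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"infeasible {name} bounds: [{lo}, {hi}]")

    def vectors(self, n_components: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.tile([self.amplitude[0], self.delay[0], self.length[0]],
                     n_components)
        hi = np.tile([self.amplitude[1], self.delay[1], self.length[1]],
                     n_components)
        return lo, hi


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings.

    The inertia weight and acceleration coefficients default to the
    constriction values (Clerc-Kennedy, chi = 0.7298 applied to
    c1 = c2 = 2.05), which converge reliably within the 80-iteration
    budget; the bare velocity rule with inertia 1.0 is recovered by setting
    ``inertia=1.0, c1=c2=2.0``.  ``velocity_clamp_fraction`` limits each
    velocity component to that fraction of its bound range; setting
    ``velocity_clamp_final`` lower makes the clamp decay linearly over the
    run (constant by default).
    """

    population: int = 1000
    max_iterations: int = 80
    c1: float = 1.4961987852200561
    c2: float = 1.4961987852200561
    inertia: float = 0.7298437881283576
    velocity_clamp_fraction: float = 0.2
    velocity_clamp_final: float = 0.2
    n_components: int = 5
    seed: int = 0
    early_stop_patience: int | None = None  # iterations without improvement

    def validate(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration coefficients must be >= 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class SwarmState:
    """Complete swarm state after ``iteration`` update steps."""

    positions: np.ndarray
    velocities: np.ndarray
    personal_best: np.ndarray
    personal_best_scores: np.ndarray
    global_best: np.ndarray
    global_best_score: float
    iteration: int
    rng: np.random.Generator


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def composite_objective(target: Waveform | np.ndarray,
                        candidate: Waveform | np.ndarray,
                        w1: float = 1.0, w2: float = 1.0) -> float:
    """Composite correlation + normalized-MSE discrepancy (minimize).

    ``J = w1 * (1 - r) + w2 * sum((t - c)^2) / sum(t^2)`` with ``r`` the
    Pearson correlation.  ``J >= 0`` and ``J == 0`` iff the candidate
    equals the target.
    """
    t = target.samples if isinstance(target, Waveform) else np.asarray(target)
    c = (candidate.samples if isinstance(candidate, Waveform)
         else np.asarray(candidate))
    if t.shape != c.shape:
        raise ValueError("target and candidate must have equal length")
    energy = float(t @ t)
    if energy == 0:
        raise ValueError("zero-energy target: NMSE is undefined")
    return float(_objective_rows(t, c[None, :], w1, w2)[0])


def _objective_rows(t: np.ndarray, rows: np.ndarray,
                    w1: float = 1.0, w2: float = 1.0) -> np.ndarray:
    """Vectorized objective of many candidates against one target."""
    tc = t - t.mean()
    tss = tc @ tc
    c = rows - rows.mean(axis=1, keepdims=True)
    denom = np.sqrt((c * c).sum(axis=1) * tss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (c @ tc) / np.where(denom > 0, denom, 1.0), 0.0)
    nmse = ((t - rows) ** 2).sum(axis=1) / (t @ t)
    out = w1 * (1.0 - r) + w2 * nmse
    return np.where(np.isfinite(out), out, np.inf)


def waveform_metrics(target: np.ndarray, candidate: np.ndarray):
    """Pearson correlation and RMSE between two equal-length signals."""
    t = np.asarray(target, float)
    c = np.asarray(candidate, float)
    tc, cc = t - t.mean(), c - c.mean()
    r = float((cc @ tc) / np.sqrt((cc @ cc) * (tc @ tc)))
    rmse = float(np.sqrt(np.mean((t - c) ** 2)))
    return r, rmse


# ---------------------------------------------------------------------------
# swarm mechanics
# ---------------------------------------------------------------------------


def init_swarm(objective, config: PSOConfig, lo: np.ndarray, hi: np.ndarray,
               rng: np.random.Generator | None = None) -> SwarmState:
    """Latin-hypercube positions, zero velocities, evaluated bests."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    pop, dim = config.population, lo.size
    strata = np.tile(np.arange(pop), (dim, 1))
    u = (rng.permuted(strata, axis=1).T + rng.random((pop, dim))) / pop
    x = lo + u * (hi - lo)
    f = np.asarray(objective(x), dtype=float)
    f = np.where(np.isfinite(f), f, np.inf)
    gi = int(np.argmin(f))
    return SwarmState(
        positions=x, velocities=np.zeros((pop, dim)),
        personal_best=x.copy(), personal_best_scores=f.copy(),
        global_best=x[gi].copy(), global_best_score=float(f[gi]),
        iteration=0, rng=rng,
    )


def pso_update(state: SwarmState, objective, config: PSOConfig,
               lo: np.ndarray, hi: np.ndarray) -> SwarmState:
    """One velocity/position/best update step (in place, returns state).

    Velocities follow ``v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)``
    with fresh per-dimension uniform ``r1, r2``; they are clamped to the
    (schedule-interpolated) fraction of each bound range, positions advance
    by one velocity step and reflect off the bounds.  Non-finite objective
    values demote the particle's score to +inf with a warning.  Ties keep
    the lower particle index (determinism).
    """
    x, v = state.positions, state.velocities
    pop, dim = x.shape
    frac = state.iteration / max(1, config.max_iterations - 1)
    frac = min(frac, 1.0)
    clamp = (config.velocity_clamp_fraction
             + (config.velocity_clamp_final
                - config.velocity_clamp_fraction) * frac)
    vmax = clamp * (hi - lo)
    r1 = state.rng.random((pop, dim))
    r2 = state.rng.random((pop, dim))
    v = (config.inertia * v
         + config.c1 * r1 * (state.personal_best - x)
         + config.c2 * r2 * (state.global_best[None, :] - x))
    v = np.clip(v, -vmax, vmax)
    x = x + v
    over, under = x > hi, x < lo
    x = np.where(over, 2 * hi - x, x)
    x = np.where(under, 2 * lo - x, x)
    v = np.where(over | under, -v, v)
    x = np.clip(x, lo, hi)

    f = np.asarray(objective(x), dtype=float)
    bad = ~np.isfinite(f)
    if bad.any():
        logger.warning("%d particle(s) returned a non-finite objective; "
                       "scored as +inf", int(bad.sum()))
        f = np.where(bad, np.inf, f)

    improved = f < state.personal_best_scores
    state.personal_best[improved] = x[improved]
    state.personal_best_scores[improved] = f[improved]
    gi = int(np.argmin(state.personal_best_scores))
    if state.personal_best_scores[gi] < state.global_best_score:
        state.global_best_score = float(state.personal_best_scores[gi])
        state.global_best = state.personal_best[gi].copy()
    state.positions, state.velocities = x, v
    state.iteration += 1
    return state


def minimize_pso(objective, config: PSOConfig, lo: np.ndarray,
                 hi: np.ndarray):
    """Run a full swarm; returns ``(best_x, best_f, history, trajectory)``.

    ``history[i]`` is the global-best objective after iteration ``i``;
    ``trajectory[i]`` is the global-best position (useful for convergence
    plots).  The global best is non-increasing by construction.
    """
    if np.any(lo >= hi):
        raise ValueError("infeasible bounds: lower >= upper")
    state = init_swarm(objective, config, lo, hi)
    history, traj = [], []
    stagnant = 0
    for _ in range(config.max_iterations):
        prev = state.global_best_score
        pso_update(state, objective, config, lo, hi)
        history.append(state.global_best_score)
        traj.append(state.global_best.copy())
        if config.early_stop_patience is not None:
            stagnant = stagnant + 1 if state.global_best_score >= prev else 0
            if stagnant >= config.early_stop_patience:
                break
    return (state.global_best.copy(), state.global_best_score,
            np.array(history), np.array(traj))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class WaveletInversion:
    """Wavelet-synthesis model fitted to a target waveform by PSO.

    Parameters
    ----------
    target : Waveform
        The call to reproduce; length must equal the synthesis window.
        Peak-normalized internally if needed (logged).
    mother : MotherWavelet, optional
        Pulse prototype; defaults to the fk14-type wavelet at level 8.
    config, bounds
        Swarm settings and parameter search space.
    strategy : {"joint", "greedy", "hybrid"}
        ``"joint"`` (default) optimizes all ``3N`` parameters in one
        swarm — the faithful single-stage protocol.  ``"greedy"`` fits
        components sequentially against the running residual
        (matching-pursuit style) with proportionally reduced swarms.
        ``"hybrid"`` runs the greedy stage first and then a joint swarm
        with half the particles warm-started around the greedy solution;
        it is the most reliable estimator for unknown calls, where the
        joint swarm alone can settle in a wrong component assignment.
    """

    def __init__(self, target: Waveform, mother: MotherWavelet | None = None,
                 config: PSOConfig | None = None,
                 bounds: SearchBounds | None = None,
                 objective_weights: tuple[float, float] = (1.0, 1.0),
                 strategy: str = "joint"):
        self.mother = mother or build_mother_wavelet()
        self.config = config or PSOConfig()
        self.bounds = bounds or SearchBounds()
        self.bounds.validate()
        self.config.validate()
        self.w1, self.w2 = objective_weights
        if strategy not in ("joint", "greedy", "hybrid"):
            raise ValueError("strategy must be 'joint', 'greedy' or "
                             "'hybrid'")
        self.strategy = strategy
        t = np.asarray(target.samples, dtype=float)
        if not np.any(t):
            raise ValueError("zero-energy target: NMSE is undefined")
        peak = np.max(np.abs(t))
        if abs(peak - 1.0) > 1e-12:
            logger.info("target not peak-normalized (peak %.4g); "
                        "normalizing internally", peak)
            t = t / peak
        self.target = Waveform(t, target.fs, "normalized")
        self.window_samples = len(t)

    # -- fitting ------------------------------------------------------------

    def _objective(self, positions: np.ndarray) -> np.ndarray:
        rows = synthesize_positions(positions, self.mother,
                                    self.window_samples, self.target.fs)
        return _objective_rows(self.target.samples, rows, self.w1, self.w2)

    def fit(self, seed: int | None = None) -> "InversionResults":
        config = self.config if seed is None else replace(self.config,
                                                          seed=seed)
        lo, hi = self.bounds.vectors(config.n_components)
        if self.strategy == "greedy":
            best, history, traj = self._fit_greedy(config)
        elif self.strategy == "hybrid":
            best, history, traj = self._fit_hybrid(config, lo, hi)
        else:
            best, _, history, traj = minimize_pso(self._objective, config,
                                                  lo, hi)
        spec = SynthesisSpec.from_vector(best, fs=self.target.fs,
                                         window_samples=self.window_samples)
        spec.components.sort(key=lambda c: c.delay)
        return InversionResults(self, spec, history, traj, config)

    def _fit_greedy(self, config: PSOConfig):
        """Sequential one-component fits against the running residual."""
        residual = self.target.samples.copy()
        lo1, hi1 = self.bounds.vectors(1)
        sub = replace(config,
                      population=max(2, config.population
                                     // config.n_components),
                      n_components=1)
        parts, histories, trajs = [], [], []
        for i in range(config.n_components):
            res = residual

            def obj(positions, res=res):
                rows = synthesize_positions(positions, self.mother,
                                            self.window_samples,
                                            self.target.fs)
                return _objective_rows(res, rows, self.w1, self.w2)

            sub_i = replace(sub, seed=sub.seed + i)
            best, _, hist, traj = minimize_pso(obj, sub_i, lo1, hi1)
            parts.append(best)
            histories.append(hist)
            trajs.append(traj)
            rendered = synthesize_positions(best, self.mother,
                                            self.window_samples,
                                            self.target.fs)[0]
            residual = residual - rendered
        best = np.concatenate(parts)
        # stage histories are per-residual; report the final full objective
        full = self._objective(best[None, :])[0]
        history = np.concatenate(histories)
        history[-1] = full
        traj = np.tile(best, (len(history), 1))
        return best, history, traj

    def _backfit(self, x: np.ndarray, config: PSOConfig,
                 cycles: int = 1) -> np.ndarray:
        """Cyclic re-fit of each component against the others' residual.

        A small one-component swarm refits component ``i`` to
        ``target - sum(others)``; the update is kept only when the full
        joint objective improves, so the refinement is monotone in J.
        """
        lo1, hi1 = self.bounds.vectors(1)
        n = x.size // 3
        x = x.copy()
        for cyc in range(cycles):
            for i in range(n):
                others = [x[3 * j:3 * j + 3] for j in range(n) if j != i]
                rendered = (synthesize_positions(
                    np.concatenate(others)[None, :], self.mother,
                    self.window_samples, self.target.fs)[0]
                    if others else 0.0)
                resid = self.target.samples - rendered
                if not np.any(resid):
                    continue

                def obj(p, resid=resid):
                    rows = synthesize_positions(p, self.mother,
                                                self.window_samples,
                                                self.target.fs)
                    return _objective_rows(resid, rows, self.w1, self.w2)

                sub = replace(config, population=150, max_iterations=60,
                              n_components=1,
                              seed=config.seed + 17 + 7 * cyc + i)
                best, _, _, _ = minimize_pso(obj, sub, lo1, hi1)
                cand = x.copy()
                cand[3 * i:3 * i + 3] = best
                if self._objective(cand[None, :])[0] < \
                        self._objective(x[None, :])[0]:
                    x = cand
        return x

    def _fit_hybrid(self, config: PSOConfig, lo: np.ndarray,
                    hi: np.ndarray, warm_fraction: float = 0.5,
                    warm_spread: float = 0.03):
        """Greedy deflation + backfitting, then a warm-started joint swarm.

        Half of the joint swarm starts within ``warm_spread`` of the
        refined greedy estimate (which is itself included as a particle,
        so the joint stage can only improve on it in objective terms);
        the other half explores the full space as usual.  A final
        backfitting cycle polishes the joint solution.
        """
        x0, g_hist, _ = self._fit_greedy(config)
        x0 = self._backfit(x0, config, cycles=2)
        joint_cfg = replace(config, seed=config.seed + 1)
        state = init_swarm(self._objective, joint_cfg, lo, hi)
        half = max(1, int(warm_fraction * joint_cfg.population))
        span = hi - lo
        near = np.clip(
            x0[None, :] + state.rng.uniform(-warm_spread, warm_spread,
                                            (half, lo.size)) * span,
            lo, hi)
        state.positions[:half] = near
        state.positions[0] = x0
        f = np.asarray(self._objective(state.positions), dtype=float)
        f = np.where(np.isfinite(f), f, np.inf)
        state.personal_best = state.positions.copy()
        state.personal_best_scores = f.copy()
        gi = int(np.argmin(f))
        state.global_best = state.positions[gi].copy()
        state.global_best_score = float(f[gi])
        history, traj = [], []
        for _ in range(joint_cfg.max_iterations):
            pso_update(state, self._objective, joint_cfg, lo, hi)
            history.append(state.global_best_score)
            traj.append(state.global_best.copy())
        best = self._backfit(state.global_best, config, cycles=1)
        best_J = float(self._objective(best[None, :])[0])
        history = np.concatenate([g_hist, np.array(history), [best_J]])
        traj = np.array(traj)
        pad = np.tile(traj[0], (len(g_hist), 1))
        return best, history, np.vstack([pad, traj, best[None, :]])


class InversionResults:
    """Estimates and diagnostics of a :class:`WaveletInversion` fit."""

    def __init__(self, model: WaveletInversion, best_spec: SynthesisSpec,
                 objective_history: np.ndarray,
                 gbest_trajectory: np.ndarray, config: PSOConfig):
        self.model = model
        self.best_spec = best_spec
        self.objective_history = np.asarray(objective_history)
        self.gbest_trajectory = np.asarray(gbest_trajectory)
        self.config = config
        # metrics are recomputed from the returned spec, not swarm caches
        self.reconstruction = synthesize_call(best_spec, model.mother)
        self.final_correlation, self.final_rmse = waveform_metrics(
            model.target.samples, self.reconstruction.samples)
        self.final_objective = composite_objective(
            model.target, self.reconstruction, model.w1, model.w2)

    # -- accessors ----------------------------------------------------------

    @property
    def parameter_trajectories(self):
        """Per-iteration global-best parameters, shape (iters, N, 3).

        Column order per component: amplitude, delay, length.
        """
        n_iter = self.gbest_trajectory.shape[0]
        return self.gbest_trajectory.reshape(n_iter, -1, 3)

    def trajectories_frame(self):
        """Long-format DataFrame: iteration, component, field, value."""
        import pandas as pd

        t = self.parameter_trajectories
        rows = []
        for it in range(t.shape[0]):
            for c in range(t.shape[1]):
                rows.append((it, c, *t[it, c],
                             self.objective_history[it]))
        return pd.DataFrame(
            rows, columns=["iteration", "component", "amplitude", "delay",
                           "length", "objective"])

    def summary(self) -> str:
        lines = [
            "Wavelet inversion results",
            "=" * 60,
            f"components:        {len(self.best_spec.components)}",
            f"population:        {self.config.population}",
            f"iterations run:    {len(self.objective_history)}",
            f"seed:              {self.config.seed}",
            f"final objective J: {self.final_objective:.6f}",
            f"correlation r:     {self.final_correlation:.6f}",
            f"RMSE (norm.):      {self.final_rmse:.6f}",
            "-" * 60,
            f"{'comp':>4} {'amplitude':>10} {'delay':>10} {'length':>10}",
        ]
        for i, c in enumerate(self.best_spec.components, 1):
            lines.append(
                f"{i:>4} {c.amplitude:>10.4f} {c.delay:>10.2f} "
                f"{c.length:>10.1f}")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Objective history and per-parameter trajectories."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.objective_history)
        ax.set_xlabel("iteration")
        ax.set_ylabel("global-best objective J")
        ax.set_yscale("log")
        return ax


def invert_waveform(target: Waveform, config: PSOConfig | None = None,
                    bounds: SearchBounds | None = None,
                    mother: MotherWavelet | None = None,
                    strategy: str = "joint") -> InversionResults:
    """Functional wrapper: fit a :class:`WaveletInversion` and return results."""
    model = WaveletInversion(target, mother=mother, config=config,
                             bounds=bounds, strategy=strategy)
    return model.fit()


def best_of_seeds(target: Waveform, seeds, config: PSOConfig | None = None,
                  bounds: SearchBounds | None = None,
                  mother: MotherWavelet | None = None) -> InversionResults:
    """Run one fit per seed and return the lowest-objective result."""
    model = WaveletInversion(target, mother=mother, config=config,
                             bounds=bounds)
    results = [model.fit(seed=int(s)) for s in seeds]
    return min(results, key=lambda r: r.final_objective)
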