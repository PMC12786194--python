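"""Swarm optimizers for multilevel Otsu thresholding.

The central algorithm is a two-phase hybrid: a sand-cat swarm (SCSO)
exploration phase runs for the first ``floor(lambda * Tmax)`` iterations,
then its incumbent best threshold vector is handed to a whale-optimization
(WOA) exploitation phase that runs the remaining iterations on a freshly
randomized population seeded with that carried-over best.  The switch
ratio ``lambda`` (default 0.6) splits the iteration budget between global
exploration and local refinement.

Canonical PSO, GWO, WOA and SCSO baselines share the same evaluation
contract: one objective evaluation per agent at initialization plus one
per agent per iteration, i.e. exactly ``N * (Tmax + 1)`` evaluations,
so fitness traces from different optimizers are directly comparable.

All randomness flows through a single ``numpy`` Generator seeded from the
configuration; identical (config, histogram, k, seed) reproduce
bit-identical thresholds and traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .otsu import Histogram, ThresholdSet, evaluate_thresholds

__all__ = [
    "HybridConfig",
    "Population",
    "FitnessTrace",
    "scso_step",
    "woa_step",
    "run_scsowoa",
    "run_baseline",
    "BASELINES",
]

BASELINES = ("pso", "gwo", "woa", "scso")


@dataclass(frozen=True)
class HybridConfig:
    """Configuration shared by the hybrid and the baselines.

    Parameters
    ----------
    population_size : int
        Number of agents N (default 30).
    total_iterations : int
        Iteration budget Tmax (default 100).
    switch_ratio : float
        Fraction of iterations given to the SCSO phase (default 0.6).
    a0 : float
        Initial value of the linearly decreasing WOA/GWO coefficient.
    spiral_b : float
        Shape constant of the logarithmic spiral move.
    scso_update_mode : {"equation", "mean_attraction"}
        "equation": each sand cat moves by either
        ``X + r1*X* - r2*X`` or ``X + r3*(X* - X)`` (fair coin per agent).
        "mean_attraction": single rule
        ``X + r1*(mean - X) + r2*(X* - X)`` pulling toward the population
        mean and the best.  Both readings circulate for this update; the
        equation form is the default.
    woa_branch_mode : {"canonical", "pseudocode"}
        "canonical": per-agent coin chooses spiral vs. encircle/search,
        with |A| deciding encircle-vs-search (standard WOA).
        "pseudocode": pure |A| branch with no spiral move.
    scso_theta_enabled : bool
        When True the orientation angle theta_i (advanced every SCSO
        iteration by ``alpha * sin(omega*t + phi)``) modulates the r3
        attraction step by ``|sin(theta_i)|``.  Disabled by default:
        orientations are tracked and reported only.
    rng_seed : int
        Seed for the run's single random stream.
    log_draws : bool
        Record every random draw per iteration (for replay testing).
    """

    population_size: int = 30
    total_iterations: int = 100
    switch_ratio: float = 0.6
    a0: float = 2.0
    spiral_b: float = 1.0
    scso_update_mode: str = "equation"
    woa_branch_mode: str = "canonical"
    scso_theta_enabled: bool = False
    theta_amplitude: float = 1.0
    theta_frequency: float = 0.2
    theta_phase: float = 0.0
    pso_inertia: float = 0.5
    pso_cognitive: float = 2.0
    pso_social: float = 2.0
    rng_seed: int = 0
    log_draws: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.total_iterations < 1:
            raise ValueError("total_iterations must be >= 1")
        if not 0.0 <= self.switch_ratio <= 1.0:
            raise ValueError("switch_ratio must lie in [0, 1]")
        if self.scso_update_mode not in ("equation", "mean_attraction"):
            raise ValueError("unknown scso_update_mode")
        if self.woa_branch_mode not in ("canonical", "pseudocode"):
            raise ValueError("unknown woa_branch_mode")

    def phase_split(self) -> tuple[int, int]:
        """(T_scso, T_woa) = (floor(lambda*Tmax), remainder)."""
        t_scso = math.floor(self.switch_ratio * self.total_iterations)
        return t_scso, self.total_iterations - t_scso

    def with_seed(self, seed: int) -> "HybridConfig":
        return replace(self, rng_seed=int(seed))


@dataclass
class Population:
    """Agent state threaded through the step functions."""

    positions: np.ndarray  # (N, d)
    fitness: np.ndarray  # (N,)
    best_position: np.ndarray  # (d,)
    best_fitness: float
    rng: np.random.Generator
    objective: object  # callable (n, d) -> (n,)
    bounds: tuple[float, float]
    theta: np.ndarray | None = None
    n_evals: int = 0
    draw_log: list = field(default_factory=list)

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        fit = np.atleast_1d(self.objective(positions))
        self.n_evals += fit.size
        return fit

    def update_best(self) -> None:
        """Adopt the best agent only on strict improvement (ties keep the
        incumbent, for determinism)."""
        i = int(np.argmax(self.fitness))
        if self.fitness[i] > self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_position = self.positions[i].copy()


@dataclass
class FitnessTrace:
    """Per-iteration best objective values with phase labels."""

    best_fitness: list = field(default_factory=list)
    phase: list = field(default_factory=list)
    n_evals: list = field(default_factory=list)

    def record(self, best: float, phase: str, n_evals: int) -> None:
        self.best_fitness.append(float(best))
        self.phase.append(phase)
        self.n_evals.append(int(n_evals))

    @property
    def total_evaluations(self) -> int:
        return self.n_evals[-1] if self.n_evals else 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.best_fitness) + 1),
                "phase": self.phase,
                "best_fitness": self.best_fitness,
                "n_evals": self.n_evals,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _clamp(positions: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    # Hard clamp; also catches non-finite excursions.
    lo, hi = bounds
    return np.clip(np.nan_to_num(positions, nan=lo, posinf=hi, neginf=lo), lo, hi)


def _check_fitness(fit: np.ndarray) -> np.ndarray:
    if np.any(np.isnan(fit)):
        raise FloatingPointError("NaN fitness encountered")
    return fit


def scso_step(pop: Population, cfg: HybridConfig, t: int) -> Population:
    """One sand-cat exploration iteration (in place).

    In "equation" mode each agent flips a fair coin between the two
    published moves: ``X + r1*X* - r2*X`` (directional hunting) and
    ``X + r3*(X* - X)`` (attraction along the difference vector), with
    r1, r2, r3 ~ U(0,1) drawn per agent.  In "mean_attraction" mode the
    single rule ``X + r1*(mean - X) + r2*(X* - X)`` applies.  All agents
    move, then all are re-evaluated, then the best is updated.
    """
    rng = pop.rng
    N, d = pop.positions.shape
    X = pop.positions
    best = pop.best_position
    if cfg.scso_update_mode == "equation":
        coin = rng.random(N)
        r1 = rng.random(N)
        r2 = rng.random(N)
        r3 = rng.random(N)
        if pop.theta is None:
            pop.theta = np.full(N, cfg.theta_phase, dtype=float)
        pop.theta = pop.theta + cfg.theta_amplitude * math.sin(
            cfg.theta_frequency * t + cfg.theta_phase
        )
        r3_eff = r3 * np.abs(np.sin(pop.theta)) if cfg.scso_theta_enabled else r3
        hunt = X + r1[:, None] * best[None, :] - r2[:, None] * X
        attract = X + r3_eff[:, None] * (best[None, :] - X)
        new = np.where((coin < 0.5)[:, None], hunt, attract)
        if cfg.log_draws:
            pop.draw_log.append(
                {"phase": "scso", "t": t, "coin": coin, "r1": r1, "r2": r2, "r3": r3}
            )
    else:
        r1 = rng.random(N)
        r2 = rng.random(N)
        mean = X.mean(axis=0)
        new = (
            X
            + r1[:, None] * (mean[None, :] - X)
            + r2[:, None] * (best[None, :] - X)
        )
        if cfg.log_draws:
            pop.draw_log.append({"phase": "scso", "t": t, "r1": r1, "r2": r2})
    pop.positions = _clamp(new, pop.bounds)
    pop.fitness = _check_fitness(pop.evaluate(pop.positions))
    pop.update_best()
    return pop


def woa_step(pop: Population, cfg: HybridConfig, t: int, t_phase: int) -> Population:
    """One whale exploitation iteration (in place).

    The coefficient ``a`` decreases linearly from ``a0`` to 0 across the
    phase: ``a = a0 * (1 - t / t_phase)``.  Per agent, scalar draws give
    ``A = 2a*r - a`` and ``C = 2*r'``.  Canonical mode: a coin p chooses
    the spiral move (p >= 0.5) or the A-branch (p < 0.5), where |A| < 1
    encircles the best and |A| >= 1 searches around a random agent.
    Pseudocode mode drops the spiral and branches on |A| alone (one shared
    r for A and C).
    """
    if t_phase <= 0:
        raise ValueError("WOA step invoked with an empty phase")
    rng = pop.rng
    N, d = pop.positions.shape
    X = pop.positions
    best = pop.best_position
    a = cfg.a0 * (1.0 - t / t_phase)
    if cfg.woa_branch_mode == "canonical":
        p = rng.random(N)
        r_a = rng.random(N)
        r_c = rng.random(N)
        ell = rng.uniform(-1.0, 1.0, N)
        rand_idx = rng.integers(0, N, N)
        A = 2.0 * a * r_a - a
        C = 2.0 * r_c
        encircle = best[None, :] - A[:, None] * np.abs(
            C[:, None] * best[None, :] - X
        )
        Xr = X[rand_idx]
        search = Xr - A[:, None] * np.abs(C[:, None] * Xr - X)
        spiral = (
            np.abs(best[None, :] - X)
            * np.exp(cfg.spiral_b * ell)[:, None]
            * np.cos(2.0 * np.pi * ell)[:, None]
            + best[None, :]
        )
        a_branch = np.where((np.abs(A) < 1.0)[:, None], encircle, search)
        new = np.where((p < 0.5)[:, None], a_branch, spiral)
        if cfg.log_draws:
            pop.draw_log.append(
                {
                    "phase": "woa",
                    "t": t,
                    "a": a,
                    "p": p,
                    "r_a": r_a,
                    "r_c": r_c,
                    "l": ell,
                    "rand_idx": rand_idx,
                }
            )
    else:
        r = rng.random(N)
        rand_idx = rng.integers(0, N, N)
        A = 2.0 * a * r - a
        C = 2.0 * r
        encircle = best[None, :] - A[:, None] * np.abs(
            C[:, None] * best[None, :] - X
        )
        Xr = X[rand_idx]
        search = Xr - A[:, None] * np.abs(C[:, None] * Xr - X)
        new = np.where((np.abs(A) < 1.0)[:, None], encircle, search)
        if cfg.log_draws:
            pop.draw_log.append(
                {"phase": "woa", "t": t, "a": a, "r": r, "rand_idx": rand_idx}
            )
    pop.positions = _clamp(new, pop.bounds)
    pop.fitness = _check_fitness(pop.evaluate(pop.positions))
    pop.update_best()
    return pop


def _make_objective(hist: Histogram):
    return lambda positions: evaluate_thresholds(hist, positions)


def _init_population(
    rng: np.random.Generator,
    objective,
    n: int,
    d: int,
    bounds: tuple[float, float],
) -> Population:
    lo, hi = bounds
    positions = rng.uniform(lo, hi, size=(n, d))
    pop = Population(
        positions=positions,
        fitness=np.empty(n),
        best_position=positions[0].copy(),
        best_fitness=-np.inf,
        rng=rng,
        objective=objective,
        bounds=bounds,
    )
    pop.fitness = _check_fitness(pop.evaluate(pop.positions))
    pop.update_best()
    return pop


def _finish(
    hist: Histogram, pop_best: np.ndarray, best_fit: float, trace: FitnessTrace
) -> tuple[ThresholdSet, float, FitnessTrace]:
    ts = ThresholdSet(pop_best.copy(), n_levels=hist.n_levels)
    return ts, float(best_fit), trace


def run_scsowoa(
    hist: Histogram, k: int, cfg: HybridConfig
) -> tuple[ThresholdSet, float, FitnessTrace]:
    """Run the adaptive hybrid SCSO -> WOA optimizer.

    The SCSO phase explores for ``floor(lambda*Tmax)`` iterations; its
    best vector seeds one agent of a fresh random WOA population that
    exploits for the remaining iterations.  The carried-over best
    guarantees the fitness trace never regresses across the handoff.
    Degenerate ratios are supported: ``lambda = 1`` skips the whale phase,
    ``lambda = 0`` replaces the exploration phase by a single random
    best-solution draw.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(cfg.rng_seed)
    bounds = (1.0, float(hist.n_levels - 1))
    objective = _make_objective(hist)
    t_scso, t_woa = cfg.phase_split()
    N = cfg.population_size
    trace = FitnessTrace()
    draw_log: list = []

    if t_scso > 0:
        pop = _init_population(rng, objective, N, k, bounds)
        pop.draw_log = draw_log
        if cfg.log_draws:
            pop.draw_log.append({"phase": "init", "positions": pop.positions.copy()})
        for t in range(1, t_scso + 1):
            scso_step(pop, cfg, t)
            trace.record(pop.best_fitness, "scso", pop.n_evals)
        best_position = pop.best_position
        best_fitness = pop.best_fitness
        n_evals = pop.n_evals
    else:
        lo, hi = bounds
        best_position = rng.uniform(lo, hi, size=k)
        best_fitness = float(objective(best_position[None, :])[0])
        n_evals = 1

    if t_woa > 0:
        lo, hi = bounds
        positions = rng.uniform(lo, hi, size=(N, k))
        positions[0] = best_position  # carry over the exploration-phase best
        pop = Population(
            positions=positions,
            fitness=np.full(N, -np.inf),
            best_position=best_position.copy(),
            best_fitness=best_fitness,
            rng=rng,
            objective=objective,
            bounds=bounds,
            n_evals=n_evals,
            draw_log=draw_log,
        )
        for t in range(1, t_woa + 1):
            woa_step(pop, cfg, t, t_woa)
            trace.record(pop.best_fitness, "woa", pop.n_evals)
        best_position = pop.best_position
        best_fitness = pop.best_fitness

    return _finish(hist, best_position, best_fitness, trace)


def _run_generic(
    hist: Histogram, k: int, cfg: HybridConfig, step
) -> tuple[ThresholdSet, float, FitnessTrace]:
    rng = np.random.default_rng(cfg.rng_seed)
    bounds = (1.0, float(hist.n_levels - 1))
    pop = _init_population(rng, _make_objective(hist), cfg.population_size, k, bounds)
    trace = FitnessTrace()
    for t in range(1, cfg.total_iterations + 1):
        step(pop, cfg, t)
        trace.record(pop.best_fitness, step.__name__.lstrip("_"), pop.n_evals)
    return _finish(hist, pop.best_position, pop.best_fitness, trace)


def _scso(pop: Population, cfg: HybridConfig, t: int) -> None:
    scso_step(pop, cfg, t)


def _woa(pop: Population, cfg: HybridConfig, t: int) -> None:
    woa_step(pop, cfg, t, cfg.total_iterations)


def _pso_state(pop: Population) -> dict:
    if not hasattr(pop, "_pso"):
        pop._pso = {
            "velocity": np.zeros_like(pop.positions),
            "pbest": pop.positions.copy(),
            "pbest_fit": pop.fitness.copy(),
        }
    return pop._pso


def _pso(pop: Population, cfg: HybridConfig, t: int) -> None:
    st = _pso_state(pop)
    rng = pop.rng
    N, d = pop.positions.shape
    u1 = rng.random((N, d))
    u2 = rng.random((N, d))
    st["velocity"] = (
        cfg.pso_inertia * st["velocity"]
        + cfg.pso_cognitive * u1 * (st["pbest"] - pop.positions)
        + cfg.pso_social * u2 * (pop.best_position[None, :] - pop.positions)
    )
    pop.positions = _clamp(pop.positions + st["velocity"], pop.bounds)
    pop.fitness = _check_fitness(pop.evaluate(pop.positions))
    improved = pop.fitness > st["pbest_fit"]
    st["pbest"][improved] = pop.positions[improved]
    st["pbest_fit"][improved] = pop.fitness[improved]
    pop.update_best()


def _gwo(pop: Population, cfg: HybridConfig, t: int) -> None:
    rng = pop.rng
    N, d = pop.positions.shape
    a = cfg.a0 * (1.0 - t / cfg.total_iterations)
    order = np.argsort(pop.fitness)[::-1]  # maximization: best first
    leaders = pop.positions[order[:3]]
    X = pop.positions
    contributions = np.zeros_like(X)
    for leader in leaders:
        A = 2.0 * a * rng.random((N, d)) - a
        C = 2.0 * rng.random((N, d))
        D = np.abs(C * leader[None, :] - X)
        contributions += leader[None, :] - A * D
    pop.positions = _clamp(contributions / 3.0, pop.bounds)
    pop.fitness = _check_fitness(pop.evaluate(pop.positions))
    pop.update_best()


_BASELINE_STEPS = {"pso": _pso, "gwo": _gwo, "woa": _woa, "scso": _scso}


def run_baseline(
    name: str, hist: Histogram, k: int, cfg: HybridConfig
) -> tuple[ThresholdSet, float, FitnessTrace]:
    """Run one of the canonical baselines (pso, gwo, woa, scso).

    Each uses the textbook update rules with the standard parameters
    (PSO: w=0.5, c1=c2=2; GWO/WOA: a linearly 2 -> 0) and the shared
    evaluation-budget contract of exactly N*(Tmax+1) objective calls.
    """
    if name not in _BASELINE_STEPS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {BASELINES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return _run_generic(hist, k, cfg, _BASELINE_STEPS[name])
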