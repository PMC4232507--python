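"""Standard firefly algorithm (FA).

The firefly algorithm is a population-based metaheuristic for global
minimization: each candidate solution ("firefly") carries a light intensity
that is an order-preserving transform of its objective value (lower objective
= brighter), and every firefly moves toward each brighter peer with an
attraction that decays with inter-firefly distance, plus a random step whose
scale is controlled by the randomization parameter ``alpha``.

Conventions used throughout the package:

* Minimization; "brighter" means a strictly lower objective value.
* Attraction between fireflies at Euclidean distance ``r`` is
  ``beta0 * exp(-gamma * (r / diag)**2)`` where ``diag`` is the diagonal of
  the search box.  Normalizing by the box diagonal makes ``gamma``
  dimensionless, so a single default works across benchmark domains that
  span ``[-1.28, 1.28]`` to ``[-600, 600]``.
* The random step multiplies per-dimension standard-normal draws by
  ``alpha`` and (by default) by the per-dimension box width.
* The double loop follows the classic formulation: positions are updated in
  place, and the moved firefly is re-evaluated and its light intensity
  updated after every move, so later comparisons within the same sweep see
  current brightness.  A firefly with no brighter peer takes only the
  random step.  Out-of-bounds coordinates are clamped to the box.
* Objective values that are not finite are recorded as ``+inf``; the firefly
  is retained.

For the analytic benchmark suite the whole sweep (including objective
evaluation) runs in a compiled kernel; arbitrary Python objectives use an
equivalent interpreted sweep.  All randomness is pre-drawn per generation
from a numpy Generator, so runs are reproducible under a seed on either
path.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .benchmarks import FUNC_IDS, BenchmarkProblem, bench_eval

__all__ = [
    "SearchSpace",
    "Firefly",
    "Population",
    "FAConfig",
    "TrialResult",
    "pairwise_distance",
    "light_intensity",
    "attractiveness",
    "fa_move",
    "fa_iterate",
    "run_fa",
    "init_population",
    "evaluate_objective",
    "alpha_linear",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(fn):
            return fn
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Axis-aligned box in R^dim."""

    dim: int
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.width))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.lower + rng.random((n, self.dim)) * self.width


@dataclass
class Firefly:
    """A candidate solution: a position and its objective value."""

    position: np.ndarray
    value: float


@dataclass
class Population:
    """Swarm state: positions, values, best-so-far record, generation count.

    ``best_value`` is the minimum objective ever observed and is
    non-increasing over generations by construction.
    """

    positions: np.ndarray          # (N, D)
    values: np.ndarray             # (N,)
    best_position: np.ndarray
    best_value: float
    generation: int = 0
    n_evaluations: int = 0

    @property
    def members(self) -> list[Firefly]:
        return [Firefly(p.copy(), float(v)) for p, v in zip(self.positions, self.values)]

    @property
    def size(self) -> int:
        return self.positions.shape[0]


@dataclass
class FAConfig:
    """Control parameters of standard FA.

    ``gamma=None`` selects the package default of 1.0 on box-diagonal
    normalized distance.  ``alpha0`` is the initial randomization parameter
    in (0, 1]; standard FA decays it linearly to ~0 over the budget.
    """

    beta0: float = 1.0
    gamma: float | None = 1.0
    alpha0: float = 0.5
    pop_size: int = 40
    max_gen: int = 1000
    seed: int = 0
    scale_by_range: bool = False

    def __post_init__(self) -> None:
        if not (self.beta0 > 0 and math.isfinite(self.beta0)):
            raise ValueError("beta0 must be positive and finite")
        if self.gamma is not None and not (self.gamma >= 0 and math.isfinite(self.gamma)):
            raise ValueError("gamma must be non-negative and finite")
        if not (0 < self.alpha0 <= 1):
            raise ValueError("alpha0 must lie in (0, 1]")
        if self.pop_size < 1 or self.max_gen < 1:
            raise ValueError("pop_size and max_gen must be positive integers")

    def resolved_gamma(self) -> float:
        return 1.0 if self.gamma is None else float(self.gamma)


@dataclass
class TrialResult:
    """Outcome of a single optimization run."""

    best_value: float
    best_position: np.ndarray
    trace: np.ndarray              # best-so-far after each generation, length max_gen
    n_evaluations: int
    wall_time: float
    flags: list = field(default_factory=list)


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def pairwise_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two position vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def light_intensity(i0: float, gamma: float, r: float) -> float:
    """Light intensity seen at distance ``r``: ``i0 * exp(-gamma * r**2)``.

    Monotonically decreasing in ``r`` for ``gamma > 0``; equals ``i0`` at
    ``r = 0`` and for all ``r`` when ``gamma = 0``.
    """
    if i0 < 0:
        raise ValueError("i0 must be non-negative")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if r < 0:
        raise ValueError("distance must be non-negative")
    return float(i0 * math.exp(-gamma * r * r))


def attractiveness(beta0: float, gamma: float, r: float) -> float:
    """Attractiveness at distance ``r``: ``beta0 * exp(-gamma * r**2)``.

    Equals ``beta0`` at ``r = 0``; constant ``beta0`` when ``gamma = 0``
    (the swarm behaves like a fully-informed PSO) and tends to 0 as
    ``gamma`` grows (pure random search).
    """
    if beta0 <= 0:
        raise ValueError("beta0 must be positive")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if r < 0:
        raise ValueError("distance must be non-negative")
    return float(beta0 * math.exp(-gamma * r * r))


def alpha_linear(alpha0: float, t: int, max_gen: int) -> float:
    """Standard-FA randomization schedule: affine decay from ``alpha0``.

    ``alpha(t) = alpha0 * (1 - (t - 1) / max_gen)`` for generations
    ``t = 1..max_gen``.
    """
    if not (1 <= t <= max_gen):
        raise ValueError("generation index out of range")
    return alpha0 * (1.0 - (t - 1) / max_gen)


def _noise_scale(space: SearchSpace, scale_by_range: bool) -> np.ndarray:
    return space.width if scale_by_range else np.ones(space.dim)


def fa_move(
    xi: np.ndarray,
    xj: np.ndarray,
    space: SearchSpace,
    cfg: FAConfig,
    rng: np.random.Generator,
    alpha: float | None = None,
) -> np.ndarray:
    """One attraction step of firefly ``xi`` toward a brighter ``xj``.

    ``x' = xi + beta(r) * (xj - xi) + alpha * scale * eps`` with
    ``eps ~ N(0, I)``; the result is clamped into the box.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if alpha is None:
        alpha = cfg.alpha0
    r = pairwise_distance(xi, xj) / space.diagonal
    beta = attractiveness(cfg.beta0, cfg.resolved_gamma(), r)
    step = beta * (xj - xi) + alpha * _noise_scale(space, cfg.scale_by_range) * rng.standard_normal(space.dim)
    return space.clip(xi + step)


# --------------------------------------------------------------------------
# compiled sweep kernel for the benchmark suite
# --------------------------------------------------------------------------

@njit(cache=True)
def _fa_sweep_bench(X, I, beta0, gscale, anoise, noise, u01, fid,
                    best_val, best_pos, lower, upper):
    # Classic double loop with in-place moves and per-move re-evaluation.
    N, D = X.shape
    evals = 0
    for i in range(N):
        moved = False
        for j in range(N):
            if I[j] < I[i]:
                moved = True
                r2 = 0.0
                for k in range(D):
                    d = X[i, k] - X[j, k]
                    r2 += d * d
                b = beta0 * np.exp(-gscale * r2)
                for k in range(D):
                    x = X[i, k] + b * (X[j, k] - X[i, k]) + anoise[k] * noise[i, j, k]
                    if x < lower[k]:
                        x = lower[k]
                    elif x > upper[k]:
                        x = upper[k]
                    X[i, k] = x
                v = bench_eval(fid, X[i], u01[i, j])
                if not np.isfinite(v):
                    v = np.inf
                I[i] = v
                evals += 1
                if v < best_val[0]:
                    best_val[0] = v
                    for k in range(D):
                        best_pos[k] = X[i, k]
        if not moved:
            for k in range(D):
                x = X[i, k] + anoise[k] * noise[i, i, k]
                if x < lower[k]:
                    x = lower[k]
                elif x > upper[k]:
                    x = upper[k]
                X[i, k] = x
            v = bench_eval(fid, X[i], u01[i, i])
            if not np.isfinite(v):
                v = np.inf
            I[i] = v
            evals += 1
            if v < best_val[0]:
                best_val[0] = v
                for k in range(D):
                    best_pos[k] = X[i, k]
    return evals


# --------------------------------------------------------------------------
# generation step (generic objectives) and full run
# --------------------------------------------------------------------------

def evaluate_objective(objective, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evaluate the objective row-wise; non-finite values become ``+inf``."""
    try:
        vals = np.asarray(objective(X, rng), dtype=float)
    except TypeError:
        vals = np.asarray(objective(X), dtype=float)
    if vals.shape != (X.shape[0],):
        raise ValueError("objective must return one value per row")
    vals = np.where(np.isfinite(vals), vals, np.inf)
    return vals


def init_population(
    space: SearchSpace, objective, cfg: FAConfig, rng: np.random.Generator
) -> Population:
    X = space.sample(cfg.pop_size, rng)
    vals = evaluate_objective(objective, X, rng)
    ibest = int(np.argmin(vals))
    return Population(
        positions=X,
        values=vals,
        best_position=X[ibest].copy(),
        best_value=float(vals[ibest]),
        generation=0,
        n_evaluations=cfg.pop_size,
    )


def _record_eval(pop: Population, i: int, v: float) -> None:
    pop.values[i] = v
    pop.n_evaluations += 1
    if v < pop.best_value:
        pop.best_value = v
        pop.best_position = pop.positions[i].copy()


def fa_iterate(
    pop: Population,
    space: SearchSpace,
    cfg: FAConfig,
    objective,
    rng: np.random.Generator,
    alpha: float | None = None,
) -> Population:
    """Advance the swarm one generation (in place) and return it.

    Interpreted equivalent of the compiled sweep, for arbitrary objectives:
    per brighter peer the firefly moves, is clamped, re-evaluated, and its
    intensity updated immediately.
    """
    N, D = pop.positions.shape
    if alpha is None:
        alpha = alpha_linear(cfg.alpha0, min(pop.generation + 1, cfg.max_gen), cfg.max_gen)
    noise = rng.standard_normal((N, N, D))
    anoise = alpha * _noise_scale(space, cfg.scale_by_range)
    gscale = cfg.resolved_gamma() / space.diagonal ** 2
    X, I = pop.positions, pop.values
    for i in range(N):
        moved = False
        for j in range(N):
            if I[j] < I[i]:
                moved = True
                diff = X[j] - X[i]
                b = cfg.beta0 * math.exp(-gscale * float(diff @ diff))
                X[i] = np.clip(X[i] + b * diff + anoise * noise[i, j], space.lower, space.upper)
                _record_eval(pop, i, float(evaluate_objective(objective, X[i:i + 1], rng)[0]))
        if not moved:
            X[i] = np.clip(X[i] + anoise * noise[i, i], space.lower, space.upper)
            _record_eval(pop, i, float(evaluate_objective(objective, X[i:i + 1], rng)[0]))
    pop.generation += 1
    return pop


def _use_kernel(problem) -> bool:
    return (
        _HAVE_NUMBA
        and isinstance(problem, BenchmarkProblem)
        and problem.index in FUNC_IDS
    )


def run_fa(problem, cfg: FAConfig) -> TrialResult:
    """Run standard FA on a problem exposing ``space`` and ``evaluate``.

    Benchmark-suite problems run on the compiled kernel; any other problem
    falls back to the interpreted sweep (identical update rules).
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    space = problem.space
    objective = problem.evaluate
    pop = init_population(space, objective, cfg, rng)
    trace = np.empty(cfg.max_gen)
    use_kernel = _use_kernel(problem)
    if use_kernel:
        fid = FUNC_IDS[problem.index]
        best_val = np.array([pop.best_value])
        best_pos = pop.best_position.copy()
        gscale = cfg.resolved_gamma() / space.diagonal ** 2
        scale = _noise_scale(space, cfg.scale_by_range)
        N, D = pop.positions.shape
        for t in range(1, cfg.max_gen + 1):
            alpha = alpha_linear(cfg.alpha0, t, cfg.max_gen)
            noise = rng.standard_normal((N, N, D))
            u01 = rng.random((N, N))
            pop.n_evaluations += _fa_sweep_bench(
                pop.positions, pop.values, cfg.beta0, gscale, alpha * scale,
                noise, u01, fid, best_val, best_pos, space.lower, space.upper,
            )
            trace[t - 1] = best_val[0]
        pop.best_value = float(best_val[0])
        pop.best_position = best_pos
    else:
        for t in range(1, cfg.max_gen + 1):
            alpha = alpha_linear(cfg.alpha0, t, cfg.max_gen)
            fa_iterate(pop, space, cfg, objective, rng, alpha=alpha)
            trace[t - 1] = pop.best_value
    return TrialResult(
        best_value=pop.best_value,
        best_position=pop.best_position,
        trace=trace,
        n_evaluations=pop.n_evaluations,
        wall_time=time.perf_counter() - t0,
    )
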