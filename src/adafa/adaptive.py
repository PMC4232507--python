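"""Adaptive firefly algorithm (AdaFa).

AdaFa extends standard FA with three cooperating mechanisms:

1. **Distance-adaptive absorption.**  Each firefly gets its own light
   absorption coefficient ``gamma_i`` derived from where it sits relative to
   the swarm: the distance ratio compares its distance to the best-so-far
   position against the smallest and largest inter-firefly distances of the
   current generation, and ``gamma_i = exp(-lam * (1 - ratio)) / delta``
   maps that ratio through the amplitude factor ``delta`` and contraction
   index ``lam``.  ``gamma_i`` is strictly positive, decreases as either
   factor grows, and blows up when both are very small.

2. **Gray-relational diversity control.**  Deng's gray relational analysis
   scores each firefly's similarity to the best-so-far reference: per
   dimension, ``xi = (dmin + rho * dmax) / (delta_k + rho * dmax)`` with the
   extreme deviations ``dmin``/``dmax`` taken over the whole population and
   all dimensions, and the weighted grade ``sum_k omega_k * xi_k`` lies in
   (0, 1].  The grade is mapped affinely onto a contraction weight
   ``g_i = g_max - grade * (g_max - g_min)`` bounded in ``[g_min, g_max]``:
   fireflies already close to the best contract hard onto it (exploitation),
   distant ones keep a loose leash (diversity).

3. **Heterogeneous update rules with decaying randomization.**  Per move one
   of two update laws is drawn uniformly at random: an FA-style attraction
   toward the brighter peer using the adaptive attractiveness, or a
   gray-weighted contraction toward the best-so-far position.  Both add a
   randomization term whose scale follows one of five nonlinear decay
   schedules S1-S5 (S0 is the linear decay of standard FA), clamped into
   ``[alpha_min, alpha_max]``.

The per-generation sweep mirrors standard FA's in-place double loop.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .benchmarks import FUNC_IDS, bench_eval
from .core import (
    FAConfig,
    Population,
    SearchSpace,
    TrialResult,
    _noise_scale,
    _record_eval,
    _use_kernel,
    attractiveness,
    evaluate_objective,
    init_population,
    njit,
    pairwise_distance,
)

__all__ = [
    "AdaptiveConfig",
    "DistanceState",
    "GrayState",
    "STRATEGIES",
    "mean_distance",
    "distance_ratio",
    "compute_distance_state",
    "adaptive_gamma",
    "adaptive_attractiveness",
    "gray_deltas",
    "gray_relational_coefficient",
    "gray_relational_grade",
    "gray_coefficient",
    "compute_gray_state",
    "alpha_schedule",
    "randomization_term",
    "heterogeneous_update",
    "adafa_iterate",
    "run_adafa",
]

STRATEGIES = ("S0", "S1", "S2", "S3", "S4", "S5")


@dataclass
class AdaptiveConfig:
    """AdaFa control parameters.

    delta : amplitude factor of the adaptive absorption coefficient (> 0).
    lam : contraction index of the adaptive absorption coefficient (> 0).
    g_min, g_max : bounds of the gray contraction coefficient.
    alpha_min, alpha_max : clamp bounds applied to the randomization scale.
    alpha_c : user constant anchoring the S1-S5 schedules at t = 1.
    decay_rate : dimensionless decay speed shared by S1 and S2.
    k_power : power of the population size in strategy S4.
    rho : gray distinguishing constant in (0, 1).
    omega : per-dimension gray weights (must sum to 1); None = uniform.
    strategy : one of S0..S5.
    """

    delta: float = 1.5
    lam: float = 0.1
    g_min: float = 0.4
    g_max: float = 0.9
    alpha_min: float = 0.0
    alpha_max: float = 1.0
    alpha_c: float = 0.9
    decay_rate: float = 35.0
    k_power: float = 0.9
    rho: float = 0.5
    omega: np.ndarray | None = None
    strategy: str = "S1"

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.lam <= 0:
            raise ValueError("delta and lam must be positive")
        if not self.g_min <= self.g_max:
            raise ValueError("g_min must not exceed g_max")
        if not self.alpha_min < self.alpha_max:
            raise ValueError("alpha_min must be below alpha_max")
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float)
            if np.any(self.omega < 0) or abs(self.omega.sum() - 1.0) > 1e-9:
                raise ValueError("omega must be non-negative and sum to 1")

    def weights(self, dim: int) -> np.ndarray:
        if self.omega is None:
            return np.full(dim, 1.0 / dim)
        if self.omega.shape != (dim,):
            raise ValueError("omega length must equal the problem dimension")
        return self.omega


@dataclass
class DistanceState:
    """Per-generation distance summary of the swarm.

    ``d_min``/``d_max`` are the global extremes of the inter-firefly
    distances; ``ratio`` locates each firefly's distance-to-best within
    that span (0 when the swarm has collapsed to a point).
    """

    mean_dist: np.ndarray
    d_best: np.ndarray
    d_max: float
    d_min: float
    ratio: np.ndarray


@dataclass
class GrayState:
    """Gray relational grades and the contraction coefficients they imply."""

    grades: np.ndarray
    coefficients: np.ndarray


# --------------------------------------------------------------------------
# distance-based adaptive absorption
# --------------------------------------------------------------------------

def mean_distance(i: int, positions: np.ndarray) -> float:
    """Average Euclidean distance from firefly ``i`` to the others."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        raise ValueError("mean distance requires at least two fireflies")
    d = np.linalg.norm(positions - positions[i], axis=1)
    return float(d.sum() / (n - 1))


def distance_ratio(state: DistanceState, i: int) -> float:
    """Position of firefly ``i``'s distance-to-best within [d_min, d_max].

    ``(d_best_i - d_min) / (d_max - d_min)``; 0 for a degenerate
    (collapsed) swarm.
    """
    if state.d_max <= state.d_min:
        return 0.0
    return float((state.d_best[i] - state.d_min) / (state.d_max - state.d_min))


def compute_distance_state(positions: np.ndarray, best_position: np.ndarray) -> DistanceState:
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        raise ValueError("distance state requires at least two fireflies")
    dm = squareform(pdist(positions))
    md = dm.sum(axis=1) / (n - 1)
    off = dm[~np.eye(n, dtype=bool)]
    d_max = float(off.max())
    d_min = float(off.min())
    d_best = np.linalg.norm(positions - np.asarray(best_position, dtype=float), axis=1)
    if d_max > d_min:
        ratio = (d_best - d_min) / (d_max - d_min)
    else:
        ratio = np.zeros(n)
    return DistanceState(mean_dist=md, d_best=d_best, d_max=d_max, d_min=d_min, ratio=ratio)


def adaptive_gamma(ratio, delta: float, lam: float):
    """Per-firefly absorption coefficient ``exp(-lam * (1 - ratio)) / delta``.

    Strictly positive; monotone non-increasing in both ``delta`` and
    ``lam`` at fixed ratio, and strictly increasing in the ratio itself, so
    fireflies far from the best see a more absorbing medium (weaker distant
    attraction) than those nearby.
    """
    if delta <= 0 or lam <= 0:
        raise ValueError("delta and lam must be positive")
    return np.exp(-lam * (1.0 - np.asarray(ratio, dtype=float))) / delta


def adaptive_attractiveness(beta0: float, gamma_i: float, r: float) -> float:
    """Attractiveness with the per-firefly ``gamma_i`` in place of a constant."""
    return attractiveness(beta0, gamma_i, r)


# --------------------------------------------------------------------------
# gray relational analysis
# --------------------------------------------------------------------------

def gray_deltas(ref: np.ndarray, comparatives: np.ndarray) -> tuple[float, float]:
    """Global min/max absolute deviation over all sequences and dimensions."""
    dev = np.abs(np.asarray(comparatives, dtype=float) - np.asarray(ref, dtype=float))
    return float(dev.min()), float(dev.max())


def gray_relational_coefficient(
    ref: np.ndarray,
    cmp: np.ndarray,
    k: int,
    rho: float,
    global_min_delta: float,
    global_max_delta: float,
) -> float:
    """Deng's gray relational coefficient at dimension ``k``.

    ``(dmin + rho * dmax) / (|ref_k - cmp_k| + rho * dmax)`` in (0, 1];
    1 when every deviation in the population is identical (degenerate guard)
    or when the deviation at ``k`` attains the global minimum.
    """
    if not (0 < rho < 1):
        raise ValueError("rho must lie in (0, 1)")
    if global_max_delta == 0.0:
        return 1.0
    delta_k = abs(float(ref[k]) - float(cmp[k]))
    return (global_min_delta + rho * global_max_delta) / (delta_k + rho * global_max_delta)


def gray_relational_grade(coefficients: np.ndarray, omega: np.ndarray) -> float:
    """Weighted gray relational grade ``sum_k omega_k * xi_k`` in (0, 1]."""
    omega = np.asarray(omega, dtype=float)
    if abs(omega.sum() - 1.0) > 1e-9:
        raise ValueError("gray weights must sum to 1")
    return float(np.dot(np.asarray(coefficients, dtype=float), omega))


def gray_coefficient(grade, g_min: float, g_max: float):
    """Map a grade in (0, 1] onto the contraction bound ``[g_min, g_max]``.

    Affine and decreasing: grade 1 (identical to the reference) gives
    ``g_min`` (strongest contraction onto the best), grade -> 0 approaches
    ``g_max`` (loosest leash, preserving diversity).
    """
    if g_min > g_max:
        raise ValueError("g_min must not exceed g_max")
    return g_max - np.asarray(grade, dtype=float) * (g_max - g_min)


def compute_gray_state(
    positions: np.ndarray, reference: np.ndarray, cfg: AdaptiveConfig
) -> GrayState:
    positions = np.asarray(positions, dtype=float)
    reference = np.asarray(reference, dtype=float)
    dev = np.abs(positions - reference)
    dmin, dmax = float(dev.min()), float(dev.max())
    if dmax == 0.0:
        coeffs = np.ones_like(dev)
    else:
        coeffs = (dmin + cfg.rho * dmax) / (dev + cfg.rho * dmax)
    grades = coeffs @ cfg.weights(positions.shape[1])
    return GrayState(grades=grades, coefficients=gray_coefficient(grades, cfg.g_min, cfg.g_max))


# --------------------------------------------------------------------------
# randomization-parameter strategies
# --------------------------------------------------------------------------

def alpha_schedule(
    strategy: str,
    t: int,
    T: int,
    N: int,
    D: int,
    cfg: AdaptiveConfig,
    alpha0: float | None = None,
) -> float:
    """Randomization-parameter value at generation ``t`` of ``T``.

    All schedules are anchored at ``u = (t - 1) / T``:

    * S0: ``a0 * (1 - u)`` - the affine decay of standard FA.
    * S1: ``ac * exp(-c * u)`` - plain exponential decay.
    * S2: ``ac * exp(-c * u**2)`` - slow start, steep finish.
    * S3: ``ac * exp(-u * sqrt(N * D))`` - decay speed set by the
      population size and the problem size.
    * S4: ``ac * exp(-u * N**k)`` - decay speed a power of the population
      size.
    * S5: ``ac * (1 + (N / D) * (1 - u)) * exp(-u * D)`` - population-size
      dependent early range whose endpoint ``ac * exp(-D)`` depends on the
      problem size only.

    S1-S5 all span a strictly larger range over ``t = 1..T`` than S0 under
    identical settings, giving stronger exploration early and far finer
    exploitation steps late.
    """
    if not (1 <= t <= T):
        raise ValueError("generation index out of range")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    u = (t - 1) / T
    ac = cfg.alpha_c
    c = cfg.decay_rate
    if strategy == "S0":
        a0 = ac if alpha0 is None else alpha0
        return a0 * (1.0 - u)
    if strategy == "S1":
        return ac * math.exp(-c * u)
    if strategy == "S2":
        return ac * math.exp(-c * u * u)
    if strategy == "S3":
        return ac * math.exp(-u * math.sqrt(N * D))
    if strategy == "S4":
        return ac * math.exp(-u * N ** cfg.k_power)
    # S5
    return ac * (1.0 + (N / D) * (1.0 - u)) * math.exp(-u * D)


def clamp_alpha(alpha: float, cfg: AdaptiveConfig) -> float:
    return min(max(alpha, cfg.alpha_min), cfg.alpha_max)


def randomization_term(
    alpha: float,
    cfg: AdaptiveConfig,
    rng: np.random.Generator,
    space: SearchSpace,
    scale_by_range: bool = True,
) -> np.ndarray:
    """Zero-mean random step: clamped alpha times scaled normal draws."""
    a = clamp_alpha(alpha, cfg)
    scale = space.width if scale_by_range else np.ones(space.dim)
    return a * scale * rng.standard_normal(space.dim)


# --------------------------------------------------------------------------
# heterogeneous update rules
# --------------------------------------------------------------------------

def heterogeneous_update(
    xi: np.ndarray,
    xj: np.ndarray,
    best: np.ndarray,
    gamma_i: float,
    g_i: float,
    alpha: float,
    space: SearchSpace,
    fa_cfg: FAConfig,
    ada_cfg: AdaptiveConfig,
    rng: np.random.Generator,
    branch: int | None = None,
) -> np.ndarray:
    """One move of firefly ``xi`` under a randomly drawn update law.

    Rule 0 (attraction): ``x' = xi + beta_i(r) * (xj - xi) + L``.
    Rule 1 (gray contraction): ``x' = best + g_i * (xi - best) + L``.
    ``L`` is the randomization term; the branch is a fair coin unless
    forced via ``branch``.  The result is clamped into the box.
    """
    xi = np.asarray(xi, dtype=float)
    if branch is None:
        branch = int(rng.random() >= 0.5)
    noise = randomization_term(alpha, ada_cfg, rng, space, fa_cfg.scale_by_range)
    if branch == 0:
        r = pairwise_distance(xi, xj) / space.diagonal
        beta = adaptive_attractiveness(fa_cfg.beta0, gamma_i, r)
        new = xi + beta * (np.asarray(xj, dtype=float) - xi) + noise
    else:
        best = np.asarray(best, dtype=float)
        new = best + g_i * (xi - best) + noise
    return space.clip(new)


# --------------------------------------------------------------------------
# sweep kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _adafa_sweep_bench(X, I, beta0, gscale_i, g, anoise, noise, coin, u01, fid,
                       best_ref, best_val, best_pos, lower, upper):
    # Double loop with heterogeneous per-move rules and per-move
    # re-evaluation.  best_ref is the generation-start reference (rule B
    # anchor); best_val/best_pos track the running best-so-far record.
    N, D = X.shape
    evals = 0
    for i in range(N):
        moved = False
        for j in range(N):
            if I[j] < I[i]:
                moved = True
                if coin[i, j] < 0.5:
                    r2 = 0.0
                    for k in range(D):
                        d = X[i, k] - X[j, k]
                        r2 += d * d
                    b = beta0 * np.exp(-gscale_i[i] * r2)
                    for k in range(D):
                        x = X[i, k] + b * (X[j, k] - X[i, k]) + anoise[k] * noise[i, j, k]
                        if x < lower[k]:
                            x = lower[k]
                        elif x > upper[k]:
                            x = upper[k]
                        X[i, k] = x
                else:
                    for k in range(D):
                        x = best_ref[k] + g[i] * (X[i, k] - best_ref[k]) + anoise[k] * noise[i, j, k]
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
# generation step and full run
# --------------------------------------------------------------------------

def _generation_state(pop: Population, space: SearchSpace, fa_cfg: FAConfig,
                      ada_cfg: AdaptiveConfig):
    """Per-generation adaptive quantities: alpha, gamma_i, g_i, reference."""
    N, D = pop.positions.shape
    t = min(pop.generation + 1, fa_cfg.max_gen)
    alpha = clamp_alpha(
        alpha_schedule(ada_cfg.strategy, t, fa_cfg.max_gen, N, D, ada_cfg,
                       alpha0=fa_cfg.alpha0),
        ada_cfg,
    )
    best = pop.best_position.copy()
    if N >= 2:
        dstate = compute_distance_state(pop.positions, best)
        gammas = adaptive_gamma(dstate.ratio, ada_cfg.delta, ada_cfg.lam)
    else:
        gammas = np.full(N, adaptive_gamma(0.0, ada_cfg.delta, ada_cfg.lam))
    gstate = compute_gray_state(pop.positions, best, ada_cfg)
    return alpha, best, gammas / space.diagonal ** 2, gstate.coefficients


def adafa_iterate(
    pop: Population,
    space: SearchSpace,
    fa_cfg: FAConfig,
    ada_cfg: AdaptiveConfig,
    objective,
    rng: np.random.Generator,
) -> Population:
    """Advance the swarm one AdaFa generation (in place) and return it.

    Per generation: the best-so-far position at the start of the generation
    is the gray reference, the anchor of the distance ratios, and rule B's
    attractor; per-firefly ``gamma_i`` and ``g_i`` are recomputed, then the
    in-place double-loop sweep applies the heterogeneous update rules with
    per-move re-evaluation (interpreted path for arbitrary objectives).
    """
    N, D = pop.positions.shape
    alpha, best, gscale_i, g = _generation_state(pop, space, fa_cfg, ada_cfg)
    noise = rng.standard_normal((N, N, D))
    coin = rng.random((N, N))
    anoise = alpha * _noise_scale(space, fa_cfg.scale_by_range)
    X, I = pop.positions, pop.values
    for i in range(N):
        moved = False
        for j in range(N):
            if I[j] < I[i]:
                moved = True
                if coin[i, j] < 0.5:
                    diff = X[j] - X[i]
                    b = fa_cfg.beta0 * math.exp(-gscale_i[i] * float(diff @ diff))
                    X[i] = X[i] + b * diff + anoise * noise[i, j]
                else:
                    X[i] = best + g[i] * (X[i] - best) + anoise * noise[i, j]
                X[i] = np.clip(X[i], space.lower, space.upper)
                _record_eval(pop, i, float(evaluate_objective(objective, X[i:i + 1], rng)[0]))
        if not moved:
            X[i] = np.clip(X[i] + anoise * noise[i, i], space.lower, space.upper)
            _record_eval(pop, i, float(evaluate_objective(objective, X[i:i + 1], rng)[0]))
    pop.generation += 1
    return pop


def run_adafa(problem, fa_cfg: FAConfig, ada_cfg: AdaptiveConfig | None = None) -> TrialResult:
    """Run AdaFa on a problem exposing ``space`` and ``evaluate``.

    Benchmark-suite problems run on the compiled kernel; any other problem
    falls back to the interpreted sweep (identical update rules).
    """
    if ada_cfg is None:
        ada_cfg = AdaptiveConfig()
    t0 = time.perf_counter()
    rng = np.random.default_rng(fa_cfg.seed)
    space = problem.space
    objective = problem.evaluate
    pop = init_population(space, objective, fa_cfg, rng)
    trace = np.empty(fa_cfg.max_gen)
    if _use_kernel(problem):
        fid = FUNC_IDS[problem.index]
        best_val = np.array([pop.best_value])
        best_pos = pop.best_position.copy()
        scale = _noise_scale(space, fa_cfg.scale_by_range)
        N, D = pop.positions.shape
        for t in range(1, fa_cfg.max_gen + 1):
            alpha, best_ref, gscale_i, g = _generation_state(pop, space, fa_cfg, ada_cfg)
            noise = rng.standard_normal((N, N, D))
            coin = rng.random((N, N))
            u01 = rng.random((N, N))
            pop.n_evaluations += _adafa_sweep_bench(
                pop.positions, pop.values, fa_cfg.beta0, gscale_i, g,
                alpha * scale, noise, coin, u01, fid, best_ref,
                best_val, best_pos, space.lower, space.upper,
            )
            # keep the record on the Population so the next generation's
            # reference sees it
            pop.best_value = float(best_val[0])
            pop.best_position = best_pos.copy()
            pop.generation += 1
            trace[t - 1] = pop.best_value
    else:
        for t in range(1, fa_cfg.max_gen + 1):
            adafa_iterate(pop, space, fa_cfg, ada_cfg, objective, rng)
            trace[t - 1] = pop.best_value
    return TrialResult(
        best_value=pop.best_value,
        best_position=pop.best_position,
        trace=trace,
        n_evaluations=pop.n_evaluations,
        wall_time=time.perf_counter() - t0,
    )
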