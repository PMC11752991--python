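"""Prairie Dog Optimization (PDO) and its improved variant (IPDO).

PDO is a population metaheuristic that mimics the colony behaviour of prairie
dogs.  An iteration budget of ``T`` is split into four equal phases: two
exploratory phases in the first half (foraging guided by Levy flights, and
burrow building around the colony's best site) and two exploitative phases in
the second half (response to a food-source alarm call, and response to a
predator alarm).  With the global best position ``G``, a randomly chosen
colony member ``r``, Levy steps ``L`` and uniform draws ``u``, the position
update adopted here is

* phase 1 (t <= T/4):       ``x' = G - eCB * rho - cpd * L``
* phase 2 (t <= T/2):       ``x' = G * r * DS * L``
* phase 3 (t <= 3T/4):      ``x' = G - eCB * eps_food - cpd * u``
* phase 4 (t <= T):         ``x' = G * PE * u``

where ``cpd = (G - r) / (G + delta)`` is the cumulative effect of the colony,
``eCB = G * (rho + (x - mean(x)) / (G * (ub - lb) + delta))`` the effect of
the current best, ``DS`` the digging strength and ``PE`` the predator effect,
both decaying as ``1.5 * (1 - t/T)^(2 t/T)`` with alternating sign, and
``delta`` a tiny constant guarding divisions.  Candidate positions are
clipped to the box bounds and accepted greedily (an individual only moves to
a better position), which makes the best-so-far trace monotone
non-increasing.

The improved variant (IPDO) differs in two ways:

1. *Tent chaotic initialization* — the initial population is laid out by
   iterating the piecewise-linear Tent map instead of uniform sampling,
   giving a more evenly spread, low-discrepancy initial cover of the box.
2. *t-distribution perturbation* — after each update every individual is
   mutated multiplicatively with Student-t draws whose degrees of freedom
   equal the current iteration index: heavy tails early (escaping local
   minima), near-Gaussian late (fine local search).  Mutants are kept only
   when they improve the individual's fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import gamma, pi, sin
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .benchmarks import BenchmarkFunction

__all__ = [
    "OptimizerConfig", "OptimizationResult", "tent_sequence", "t_perturbation",
    "minimize", "compare_variants", "VariantComparison", "comparison_frame",
]

_DELTA = 2.220446049250313e-16  # tiny constant guarding divisions


@dataclass(frozen=True)
class OptimizerConfig:
    """Run configuration for :func:`minimize`.

    ``rho`` is the alarm-sound (food source) constant, ``eps_food`` the
    food-source quality scalar, ``amplitude`` the digging-strength /
    predator-effect amplitude and ``levy_exponent`` the Mantegna Levy-flight
    exponent; defaults follow the original PDO formulation.  ``patience``
    and ``target_fitness`` enable optional early termination (stalled best
    fitness, or a known attainable bound); both are off by default so the
    convergence trace has exactly ``max_iterations`` entries.
    """

    dimension: int
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    population_size: int = 30
    max_iterations: int = 200
    seed: int = 0
    variant: str = "ipdo"
    tent_alpha: float = 0.5
    mutation_probability: float = 0.5
    rho: float = 0.1
    eps_food: float = 0.1
    amplitude: float = 1.5
    levy_exponent: float = 1.5
    patience: Optional[int] = None
    target_fitness: Optional[float] = None

    def __post_init__(self):
        lo = np.broadcast_to(np.asarray(self.lower_bounds, float),
                             (self.dimension,)).copy()
        hi = np.broadcast_to(np.asarray(self.upper_bounds, float),
                             (self.dimension,)).copy()
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)
        if np.any(lo >= hi):
            raise ValueError("lower_bounds must be strictly below upper_bounds")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.variant not in ("pdo", "ipdo"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.tent_alpha < 1.0:
            raise ValueError("tent_alpha must lie in (0, 1)")
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise ValueError("mutation_probability must lie in [0, 1]")

    @classmethod
    def for_function(cls, fn: BenchmarkFunction, **kwargs) -> "OptimizerConfig":
        return cls(dimension=fn.dimension, lower_bounds=fn.lower,
                   upper_bounds=fn.upper, **kwargs)


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    convergence_trace: np.ndarray
    evaluations_used: int


def tent_sequence(n_rows: int, n_cols: int, x0: float,
                  alpha: float = 0.5) -> np.ndarray:
    """Iterate the Tent map into an ``n_rows x n_cols`` matrix in (0, 1).

    The map is ``x' = x/alpha`` for ``x < alpha`` and ``(1-x)/(1-alpha)``
    otherwise.  Rational seeds can collapse onto 0 or a fixed point; when
    the orbit leaves (0, 1) or stalls, an additive jitter of 1e-6
    (re-wrapped into the unit interval) restarts it.
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie strictly inside (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    if x0 == alpha:
        x0 = (x0 + 1e-6) % 1.0
    out = np.empty(n_rows * n_cols)
    x = x0
    for k in range(out.size):
        out[k] = x
        nxt = x / alpha if x < alpha else (1.0 - x) / (1.0 - alpha)
        # escape degenerate orbits: collapse to the boundary or a fixed point
        if not 0.0 < nxt < 1.0 or abs(nxt - x) < 1e-12:
            nxt = (nxt + 1e-6) % 1.0
            if nxt <= 0.0:
                nxt = 1e-6
        x = nxt
    return out.reshape(n_rows, n_cols)


def t_perturbation(position: np.ndarray, degrees_of_freedom: float,
                   rng: np.random.Generator,
                   mutation_probability: float = 0.5,
                   lower_bounds: Optional[np.ndarray] = None,
                   upper_bounds: Optional[np.ndarray] = None) -> np.ndarray:
    """Multiplicative Student-t mutation: ``x' = x + x * t_df`` per coordinate.

    Each coordinate is perturbed independently with probability
    ``mutation_probability``; the result is clipped to the bounds when given.
    A zero coordinate is a fixed point of the multiplicative scheme.
    """
    x = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("position must be finite")
    if degrees_of_freedom < 1:
        raise ValueError("degrees_of_freedom must be >= 1")
    draws = rng.standard_t(degrees_of_freedom, size=x.shape)
    mask = rng.random(x.shape) < mutation_probability
    out = x + np.where(mask, x * draws, 0.0)
    if lower_bounds is not None:
        out = np.clip(out, lower_bounds, upper_bounds)
    return out


def _levy_steps(rng: np.random.Generator, shape, beta: float) -> np.ndarray:
    """Mantegna's construction of symmetric Levy-stable steps."""
    sigma = (gamma(1 + beta) * sin(pi * beta / 2)
             / (gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))) ** (1 / beta)
    u = rng.normal(0.0, sigma, size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    return u / np.abs(v) ** (1 / beta)


def _evaluate_population(objective: Callable, X: np.ndarray) -> np.ndarray:
    vals = np.array([objective(row) for row in X], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~np.isfinite(vals))[0])
        raise RuntimeError(
            f"objective returned a non-finite value {vals[bad]!r} at "
            f"position {X[bad]!r}; aborting the run")
    return vals


def minimize(objective: Callable[[np.ndarray], float],
             config: OptimizerConfig) -> OptimizationResult:
    """Minimize ``objective`` over the configured box with PDO or IPDO."""
    rng = np.random.default_rng(config.seed)
    m, d = config.population_size, config.dimension
    lo, hi = config.lower_bounds, config.upper_bounds
    span = hi - lo
    T = config.max_iterations

    if config.variant == "ipdo":
        x0 = float(rng.uniform(0.05, 0.95))
        unit = tent_sequence(m, d, x0, config.tent_alpha)
    else:
        unit = rng.random((m, d))
    X = lo + unit * span
    fit = _evaluate_population(objective, X)
    evals = m
    best_idx = int(np.argmin(fit))
    gbest = X[best_idx].copy()
    gbest_fit = float(fit[best_idx])

    trace = np.empty(T)
    stall = 0
    n_done = 0
    for t in range(1, T + 1):
        mu = -1.0 if t % 2 == 0 else 1.0
        decay = (1.0 - t / T) ** (2.0 * t / T)
        ds = config.amplitude * rng.standard_normal() * decay * mu
        pe = config.amplitude * decay * mu

        r_idx = rng.integers(m, size=m)
        rpd = X[r_idx]
        cpd = (gbest[None, :] - rpd) / (gbest[None, :] + _DELTA)
        p_eff = config.rho + (X - X.mean(axis=1, keepdims=True)) \
            / (gbest[None, :] * span[None, :] + _DELTA)
        ecb = gbest[None, :] * p_eff

        if t <= T / 4:
            cand = gbest[None, :] - ecb * config.rho \
                - cpd * _levy_steps(rng, (m, d), config.levy_exponent)
        elif t <= T / 2:
            cand = gbest[None, :] * rpd * ds \
                * _levy_steps(rng, (m, d), config.levy_exponent)
        elif t <= 3 * T / 4:
            cand = gbest[None, :] - ecb * config.eps_food \
                - cpd * rng.random((m, d))
        else:
            cand = gbest[None, :] * pe * rng.random((m, d))
        np.clip(cand, lo, hi, out=cand)

        cand_fit = _evaluate_population(objective, cand)
        evals += m
        improved = cand_fit < fit
        X[improved] = cand[improved]
        fit[improved] = cand_fit[improved]

        if config.variant == "ipdo":
            df = max(1.0, float(t))
            mut = np.empty_like(X)
            for i in range(m):
                mut[i] = t_perturbation(X[i], df, rng,
                                        config.mutation_probability, lo, hi)
            mut_fit = _evaluate_population(objective, mut)
            evals += m
            better = mut_fit < fit
            X[better] = mut[better]
            fit[better] = mut_fit[better]

        it_best = int(np.argmin(fit))
        if fit[it_best] < gbest_fit - 1e-15:
            gbest_fit = float(fit[it_best])
            gbest = X[it_best].copy()
            stall = 0
        else:
            stall += 1
        trace[t - 1] = gbest_fit
        n_done = t

        if config.target_fitness is not None and gbest_fit <= config.target_fitness:
            break
        if config.patience is not None and stall >= config.patience:
            break

    return OptimizationResult(best_position=gbest, best_fitness=gbest_fit,
                              convergence_trace=trace[:n_done].copy(),
                              evaluations_used=evals)


@dataclass
class VariantComparison:
    """Paired PDO-vs-IPDO summary over matched seeds."""
    function_name: str
    repeats: int
    mean_final: dict
    std_final: dict
    mean_trace: dict


def compare_variants(fn: BenchmarkFunction, repeats: int, base_seed: int,
                     population_size: int = 30,
                     max_iterations: int = 200) -> VariantComparison:
    """Run PDO and IPDO ``repeats`` times with matched seeds on ``fn``."""
    if repeats < 2:
        raise ValueError("repeats must be at least 2")
    finals = {"pdo": [], "ipdo": []}
    traces = {"pdo": [], "ipdo": []}
    for variant in ("pdo", "ipdo"):
        for r in range(repeats):
            seed = base_seed + r
            noise_rng = (np.random.default_rng((seed * 1_000_003 + 7) % (2**31))
                         if fn.noisy else None)
            objective = (lambda x, _rng=noise_rng: fn(x, rng=_rng))
            cfg = OptimizerConfig.for_function(
                fn, population_size=population_size,
                max_iterations=max_iterations, seed=seed, variant=variant)
            res = minimize(objective, cfg)
            finals[variant].append(res.best_fitness)
            traces[variant].append(res.convergence_trace)
    return VariantComparison(
        function_name=fn.name, repeats=repeats,
        mean_final={v: float(np.mean(finals[v])) for v in finals},
        std_final={v: float(np.std(finals[v])) for v in finals},
        mean_trace={v: np.mean(np.vstack(traces[v]), axis=0) for v in traces},
    )


def comparison_frame(summary: VariantComparison) -> pd.DataFrame:
    """Tidy (function, iteration, variant, fitness) table of the mean traces."""
    parts = []
    for variant, trace in summary.mean_trace.items():
        parts.append(pd.DataFrame({
            "function": summary.function_name,
            "iteration": np.arange(1, trace.size + 1),
            "variant": variant,
            "fitness": trace,
        }))
    return pd.concat(parts, ignore_index=True)
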