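"""Classical 23-function benchmark suite for comparing metaheuristics.

The suite is the de-facto standard collection used throughout the swarm
intelligence literature: thirteen high-dimensional functions (seven unimodal,
six multimodal, dimension 30) followed by ten fixed-dimension multimodal
functions (Shekel's foxholes, Kowalik, six-hump camel back, Branin,
Goldstein-Price, the two Hartmann families and three Shekel functions).
All functions are minimization problems.

Unimodal functions probe local exploitation; multimodal functions, with their
many local minima, probe global exploration.  The quartic function carries
additive uniform noise and therefore accepts an explicit random generator;
with no generator it evaluates noise-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["BenchmarkFunction", "list_functions", "get_function", "evaluate",
           "registry_json"]

UNIMODAL = "unimodal"
MULTIMODAL = "multimodal"


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named minimization objective with box bounds and a known optimum.

    ``known_optimizer`` is ``None`` when the minimizing point is irrational /
    tabulated only numerically; ``known_optimum_value`` is then a slightly
    conservative literature floor (never above the true minimum).
    """

    name: str
    dimension: int
    lower_bound: float
    upper_bound: float
    modality: str
    known_optimum_value: float
    known_optimizer: Optional[np.ndarray] = field(default=None, repr=False)
    noisy: bool = False
    _fn: Callable[..., float] = field(default=None, repr=False, compare=False)

    @property
    def lower(self) -> np.ndarray:
        return np.full(self.dimension, self.lower_bound)

    @property
    def upper(self) -> np.ndarray:
        return np.full(self.dimension, self.upper_bound)

    def __call__(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        return evaluate(self, x, rng=rng)


def _u_penalty(x: np.ndarray, a: float, k: float, m: float) -> float:
    out = np.where(x > a, k * (x - a) ** m,
                   np.where(x < -a, k * (-x - a) ** m, 0.0))
    return float(np.sum(out))


def _sphere(x):
    return float(np.sum(x * x))


def _schwefel_222(x):
    ax = np.abs(x)
    return float(np.sum(ax) + np.prod(ax))


def _schwefel_12(x):
    return float(np.sum(np.cumsum(x) ** 2))


def _schwefel_221(x):
    return float(np.max(np.abs(x)))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _step(x):
    return float(np.sum(np.floor(x + 0.5) ** 2))


def _quartic_noise(x, rng=None):
    base = float(np.sum(np.arange(1, x.size + 1) * x ** 4))
    if rng is not None:
        base += float(rng.random())
    return base


def _schwefel_226(x):
    return float(-np.sum(x * np.sin(np.sqrt(np.abs(x)))))


def _rastrigin(x):
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _ackley(x):
    n = x.size
    s1 = np.sum(x * x) / n
    s2 = np.sum(np.cos(2.0 * np.pi * x)) / n
    return float(-20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e)


def _griewank(x):
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _penalized_1(x):
    n = x.size
    y = 1.0 + (x + 1.0) / 4.0
    core = (10.0 * np.sin(np.pi * y[0]) ** 2
            + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
            + (y[-1] - 1.0) ** 2)
    return float(np.pi / n * core + _u_penalty(x, 10.0, 100.0, 4.0))


def _penalized_2(x):
    core = (np.sin(3.0 * np.pi * x[0]) ** 2
            + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
            + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2))
    return float(0.1 * core + _u_penalty(x, 5.0, 100.0, 4.0))


_FOXHOLE_A = np.array([
    [-32, -16, 0, 16, 32] * 5,
    [-32] * 5 + [-16] * 5 + [0] * 5 + [16] * 5 + [32] * 5,
], dtype=float)


def _foxholes(x):
    d = np.sum((x[:, None] - _FOXHOLE_A) ** 6, axis=0)
    j = np.arange(1, 26)
    return float(1.0 / (1.0 / 500.0 + np.sum(1.0 / (j + d))))


_KOWALIK_A = np.array([0.1957, 0.1947, 0.1735, 0.16, 0.0844, 0.0627,
                       0.0456, 0.0342, 0.0323, 0.0235, 0.0246])
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16])


def _kowalik(x):
    b = _KOWALIK_B
    model = x[0] * (b ** 2 + b * x[1]) / (b ** 2 + b * x[2] + x[3])
    return float(np.sum((_KOWALIK_A - model) ** 2))


def _six_hump_camel(x):
    x1, x2 = x
    return float(4 * x1 ** 2 - 2.1 * x1 ** 4 + x1 ** 6 / 3.0
                 + x1 * x2 - 4 * x2 ** 2 + 4 * x2 ** 4)


def _branin(x):
    x1, x2 = x
    a, b, c = 1.0, 5.1 / (4.0 * np.pi ** 2), 5.0 / np.pi
    r, s, t = 6.0, 10.0, 1.0 / (8.0 * np.pi)
    return float(a * (x2 - b * x1 ** 2 + c * x1 - r) ** 2
                 + s * (1.0 - t) * np.cos(x1) + s)


def _goldstein_price(x):
    x1, x2 = x
    t1 = 1.0 + (x1 + x2 + 1.0) ** 2 * (19 - 14 * x1 + 3 * x1 ** 2
                                       - 14 * x2 + 6 * x1 * x2 + 3 * x2 ** 2)
    t2 = 30.0 + (2 * x1 - 3 * x2) ** 2 * (18 - 32 * x1 + 12 * x1 ** 2
                                          + 48 * x2 - 36 * x1 * x2 + 27 * x2 ** 2)
    return float(t1 * t2)


_HART3_A = np.array([[3, 10, 30], [0.1, 10, 35], [3, 10, 30], [0.1, 10, 35]], float)
_HART3_P = np.array([[0.3689, 0.117, 0.2673], [0.4699, 0.4387, 0.747],
                     [0.1091, 0.8732, 0.5547], [0.03815, 0.5743, 0.8828]])
_HART6_A = np.array([[10, 3, 17, 3.5, 1.7, 8], [0.05, 10, 17, 0.1, 8, 14],
                     [3, 3.5, 1.7, 10, 17, 8], [17, 8, 0.05, 10, 0.1, 14]], float)
_HART6_P = np.array([[0.1312, 0.1696, 0.5569, 0.0124, 0.8283, 0.5886],
                     [0.2329, 0.4135, 0.8307, 0.3736, 0.1004, 0.9991],
                     [0.2348, 0.1451, 0.3522, 0.2883, 0.3047, 0.6650],
                     [0.4047, 0.8828, 0.8732, 0.5743, 0.1091, 0.0381]])
_HART_C = np.array([1.0, 1.2, 3.0, 3.2])


def _hartmann(x, A, P):
    inner = np.sum(A * (x[None, :] - P) ** 2, axis=1)
    return float(-np.sum(_HART_C * np.exp(-inner)))


_SHEKEL_A = np.array([[4, 4, 4, 4], [1, 1, 1, 1], [8, 8, 8, 8], [6, 6, 6, 6],
                      [3, 7, 3, 7], [2, 9, 2, 9], [5, 5, 3, 3], [8, 1, 8, 1],
                      [6, 2, 6, 2], [7, 3.6, 7, 3.6]], float)
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _shekel(x, m):
    d = np.sum((x[None, :] - _SHEKEL_A[:m]) ** 2, axis=1)
    return float(-np.sum(1.0 / (d + _SHEKEL_C[:m])))


def _build_registry() -> list[BenchmarkFunction]:
    z30 = np.zeros(30)
    o30 = np.ones(30)
    F = BenchmarkFunction
    return [
        F("sphere", 30, -100, 100, UNIMODAL, 0.0, z30, _fn=_sphere),
        F("schwefel_2_22", 30, -10, 10, UNIMODAL, 0.0, z30, _fn=_schwefel_222),
        F("schwefel_1_2", 30, -100, 100, UNIMODAL, 0.0, z30, _fn=_schwefel_12),
        F("schwefel_2_21", 30, -100, 100, UNIMODAL, 0.0, z30, _fn=_schwefel_221),
        F("rosenbrock", 30, -30, 30, UNIMODAL, 0.0, o30, _fn=_rosenbrock),
        F("step", 30, -100, 100, UNIMODAL, 0.0, z30, _fn=_step),
        F("quartic_noise", 30, -1.28, 1.28, UNIMODAL, 0.0, z30, noisy=True,
          _fn=_quartic_noise),
        F("schwefel_2_26", 30, -500, 500, MULTIMODAL, -12569.5, None,
          _fn=_schwefel_226),
        F("rastrigin", 30, -5.12, 5.12, MULTIMODAL, 0.0, z30, _fn=_rastrigin),
        F("ackley", 30, -32, 32, MULTIMODAL, 0.0, z30, _fn=_ackley),
        F("griewank", 30, -600, 600, MULTIMODAL, 0.0, z30, _fn=_griewank),
        F("penalized_1", 30, -50, 50, MULTIMODAL, 0.0, -o30, _fn=_penalized_1),
        F("penalized_2", 30, -50, 50, MULTIMODAL, 0.0, o30, _fn=_penalized_2),
        F("foxholes", 2, -65.536, 65.536, MULTIMODAL, 0.998003, None, _fn=_foxholes),
        F("kowalik", 4, -5, 5, MULTIMODAL, 0.000307, None, _fn=_kowalik),
        F("six_hump_camel", 2, -5, 5, MULTIMODAL, -1.03163, None,
          _fn=_six_hump_camel),
        # Branin's customary domain is [-5,10] x [0,15]; the symmetric box
        # [-5,15] contains it and keeps per-function bounds scalar.
        F("branin", 2, -5, 15, MULTIMODAL, 10.0 / (8.0 * np.pi),
          np.array([np.pi, 2.275]), _fn=_branin),
        F("goldstein_price", 2, -2, 2, MULTIMODAL, 3.0, np.array([0.0, -1.0]),
          _fn=_goldstein_price),
        F("hartmann_3", 3, 0, 1, MULTIMODAL, -3.86279, None,
          _fn=lambda x: _hartmann(x, _HART3_A, _HART3_P)),
        F("hartmann_6", 6, 0, 1, MULTIMODAL, -3.32238, None,
          _fn=lambda x: _hartmann(x, _HART6_A, _HART6_P)),
        F("shekel_5", 4, 0, 10, MULTIMODAL, -10.1533, None,
          _fn=lambda x: _shekel(x, 5)),
        F("shekel_7", 4, 0, 10, MULTIMODAL, -10.4030, None,
          _fn=lambda x: _shekel(x, 7)),
        F("shekel_10", 4, 0, 10, MULTIMODAL, -10.5365, None,
          _fn=lambda x: _shekel(x, 10)),
    ]


_REGISTRY = _build_registry()
_BY_NAME = {f.name: f for f in _REGISTRY}


def list_functions() -> list[BenchmarkFunction]:
    """Return the 23 benchmark functions in their canonical order."""
    return list(_REGISTRY)


def get_function(name: str) -> BenchmarkFunction:
    try:
        return _BY_NAME[name]
    except KeyError:
        known = ", ".join(sorted(_BY_NAME))
        raise KeyError(f"unknown benchmark function {name!r}; known: {known}") from None


def evaluate(fn: BenchmarkFunction, point: Sequence[float],
             rng: Optional[np.random.Generator] = None) -> float:
    """Evaluate ``fn`` at ``point``.

    Raises ``ValueError`` on dimension mismatch or out-of-bounds points.
    The noisy quartic draws its additive noise from ``rng``; without a
    generator it evaluates noise-free.
    """
    x = np.asarray(point, dtype=float)
    if x.ndim != 1 or x.size != fn.dimension:
        raise ValueError(
            f"{fn.name} expects a vector of length {fn.dimension}, "
            f"got shape {x.shape}")
    if np.any(x < fn.lower_bound - 1e-12) or np.any(x > fn.upper_bound + 1e-12):
        raise ValueError(f"point outside the bounds "
                         f"[{fn.lower_bound}, {fn.upper_bound}] of {fn.name}")
    if fn.noisy:
        return fn._fn(x, rng)
    return fn._fn(x)


def registry_json() -> str:
    """Machine-readable registry export."""
    rows = [{
        "name": f.name,
        "dimension": f.dimension,
        "lower_bound": f.lower_bound,
        "upper_bound": f.upper_bound,
        "modality": f.modality,
        "known_optimum_value": f.known_optimum_value,
        "known_optimizer": (None if f.known_optimizer is None
                            else list(map(float, f.known_optimizer))),
        "noisy": f.noisy,
    } for f in _REGISTRY]
    return json.dumps(rows, indent=2)
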