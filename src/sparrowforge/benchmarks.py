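"""Classic box-constrained test objectives used to compare optimizer variants.

Fourteen minimization problems: ten 30-dimensional (Sphere, Schwefel 2.21,
Schwefel 2.22, Rosenbrock, Step, Quartic-with-noise, Alpine, Rastrigin,
Sum squares, Ackley) and four 2-dimensional (Matyas, Levi N.13, Booth,
Three-hump camel).  Every function has a known global minimum value of 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["BenchmarkFunction", "evaluate", "registry", "get_function", "registry_json"]


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named objective with its search box and known optimum.

    ``known_minimizer`` is the textbook minimizer when a closed-form one
    exists.  ``stochastic`` marks the quartic function whose definition
    includes an additive uniform[0, 1) noise term.
    """

    name: str
    label: str
    dimension: int
    lower_bound: float
    upper_bound: float
    optimum_value: float
    _evaluator: Callable[[np.ndarray], float] = field(repr=False)
    known_minimizer: Optional[np.ndarray] = None
    stochastic: bool = False

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")


def evaluate(
    fn: BenchmarkFunction,
    x: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    *,
    noise: bool = True,
) -> float:
    """Evaluate ``fn`` at point ``x``.

    Parameters
    ----------
    fn : BenchmarkFunction
    x : array-like of shape (fn.dimension,)
    rng : numpy Generator, required only for the stochastic quartic
        function when ``noise`` is enabled.
    noise : if False, the quartic noise term is suppressed so the
        evaluation is deterministic.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != fn.dimension:
        raise ValueError(
            f"{fn.label} expects a vector of length {fn.dimension}, got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates are not admissible")
    value = float(fn._evaluator(x))
    if fn.stochastic and noise:
        if rng is None:
            raise ValueError(f"{fn.label} includes a noise term; pass an rng or noise=False")
        value += float(rng.random())
    return value


# ---------------------------------------------------------------------------
# evaluators


def _sphere(x):
    return np.sum(x * x)


def _schwefel_2_21(x):
    return np.max(np.abs(x))


def _schwefel_2_22(x):
    a = np.abs(x)
    return np.sum(a) + np.prod(a)


def _rosenbrock(x):
    return np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2)


def _step(x):
    return np.sum((x + 0.5) ** 2)


def _quartic(x):
    i = np.arange(1, x.size + 1)
    return np.sum(i * x**4)


def _alpine(x):
    return np.sum(np.abs(x * np.sin(x) + 0.1 * x))


def _rastrigin(x):
    return np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0)


def _sum_squares(x):
    i = np.arange(1, x.size + 1)
    return np.sum(i * x * x)


def _ackley(x):
    d = x.size
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + math.e
    )


def _matyas(x):
    return 0.26 * (x[0] ** 2 + x[1] ** 2) - 0.48 * x[0] * x[1]


def _levi(x):
    # Levi N.13
    return (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + (x[0] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1]) ** 2)
        + (x[1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[1]) ** 2)
    )


def _booth(x):
    return (x[0] + 2.0 * x[1] - 7.0) ** 2 + (2.0 * x[0] + x[1] - 5.0) ** 2


def _three_hump(x):
    return (
        2.0 * x[0] ** 2
        - 1.05 * x[0] ** 4
        + x[0] ** 6 / 6.0
        + x[0] * x[1]
        + x[1] ** 2
    )


_REGISTRY: list[BenchmarkFunction] = [
    BenchmarkFunction("sphere", "F1", 30, -100.0, 100.0, 0.0, _sphere, np.zeros(30)),
    BenchmarkFunction("schwefel_2_21", "F2", 30, -100.0, 100.0, 0.0, _schwefel_2_21, np.zeros(30)),
    BenchmarkFunction("schwefel_2_22", "F3", 30, -10.0, 10.0, 0.0, _schwefel_2_22, np.zeros(30)),
    BenchmarkFunction("rosenbrock", "F4", 30, -30.0, 30.0, 0.0, _rosenbrock, np.ones(30)),
    BenchmarkFunction("step", "F5", 30, -100.0, 100.0, 0.0, _step, np.full(30, -0.5)),
    BenchmarkFunction("quartic", "F6", 30, -1.28, 1.28, 0.0, _quartic, np.zeros(30), stochastic=True),
    BenchmarkFunction("alpine", "F7", 30, -10.0, 10.0, 0.0, _alpine, np.zeros(30)),
    BenchmarkFunction("rastrigin", "F8", 30, -5.12, 5.12, 0.0, _rastrigin, np.zeros(30)),
    BenchmarkFunction("sum_squares", "F9", 30, -10.0, 10.0, 0.0, _sum_squares, np.zeros(30)),
    BenchmarkFunction("ackley", "F10", 30, -100.0, 100.0, 0.0, _ackley, np.zeros(30)),
    BenchmarkFunction("matyas", "F11", 2, -10.0, 10.0, 0.0, _matyas, np.zeros(2)),
    BenchmarkFunction("levi", "F12", 2, -10.0, 10.0, 0.0, _levi, np.ones(2)),
    BenchmarkFunction("booth", "F13", 2, -10.0, 10.0, 0.0, _booth, np.array([1.0, 3.0])),
    BenchmarkFunction("three_hump", "F14", 2, -10.0, 10.0, 0.0, _three_hump, np.zeros(2)),
]

_BY_KEY = {fn.label: fn for fn in _REGISTRY}
_BY_KEY.update({fn.name: fn for fn in _REGISTRY})


def registry() -> list[BenchmarkFunction]:
    """The fourteen benchmark functions in canonical F1..F14 order."""
    return list(_REGISTRY)


def get_function(key: str) -> BenchmarkFunction:
    """Look up a function by short label (``"F10"``) or name (``"ackley"``)."""
    try:
        return _BY_KEY[key]
    except KeyError:
        known = ", ".join(fn.label for fn in _REGISTRY)
        raise KeyError(f"unknown benchmark function {key!r}; known: {known}") from None


def registry_json() -> str:
    """Registry metadata (no evaluators) serialized as JSON."""
    return json.dumps(
        [
            {
                "label": fn.label,
                "name": fn.name,
                "dimension": fn.dimension,
                "lower_bound": fn.lower_bound,
                "upper_bound": fn.upper_bound,
                "optimum_value": fn.optimum_value,
            }
            for fn in _REGISTRY
        ],
        indent=2,
    )
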