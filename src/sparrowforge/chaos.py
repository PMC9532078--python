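"""Chaotic one-dimensional maps used as ergodic pseudo-random sources.

Nine named recurrences (tent, chebyshev, circle, iterative, sine, singer,
sinusoidal, logistic, cubic) drive population initialization and the
perturbation operator of the improved sparrow search loop.  Raw iterates
live in each map's native range and are rescaled to [0, 1] before being
mapped affinely into a search box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ChaoticMap",
    "ChaosStream",
    "MAP_NAMES",
    "make_map",
    "iterate_map",
    "chaotic_sequence",
    "chaos_to_domain",
    "perturb",
    "chaotic_init_population",
]

logger = logging.getLogger(__name__)

MAP_NAMES = (
    "tent",
    "chebyshev",
    "circle",
    "iterative",
    "sine",
    "singer",
    "sinusoidal",
    "logistic",
    "cubic",
)

# name -> (default params, native range of the iterates)
_DEFAULTS: dict[str, tuple[dict, tuple[float, float]]] = {
    "tent": ({"beta": 0.7}, (0.0, 1.0)),
    "chebyshev": ({"phi": 4.0}, (-1.0, 1.0)),
    "circle": ({}, (0.0, 1.0)),
    "iterative": ({"a": 0.7}, (-1.0, 1.0)),
    "sine": ({"a": 4.0}, (0.0, 1.0)),
    "singer": ({"mu": 1.07}, (0.0, 1.0)),
    "sinusoidal": ({"a": 2.3}, (0.0, 1.0)),
    "logistic": ({"mu": 4.0}, (0.0, 1.0)),
    "cubic": ({"rho": 2.595}, (0.0, 1.0)),
}


@dataclass(frozen=True)
class ChaoticMap:
    """A named chaotic recurrence with fixed parameters."""

    name: str
    params: dict = field(default_factory=dict)
    native_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.name not in _DEFAULTS:
            raise ValueError(f"unknown chaotic map {self.name!r}; known: {MAP_NAMES}")


def make_map(name: str, **params: float) -> ChaoticMap:
    """Build a map with defaults filled in for unspecified parameters."""
    if name not in _DEFAULTS:
        raise ValueError(f"unknown chaotic map {name!r}; known: {MAP_NAMES}")
    defaults, native = _DEFAULTS[name]
    merged = {**defaults, **params}
    unknown = set(merged) - set(defaults)
    if unknown:
        raise ValueError(f"map {name!r} does not take parameters {sorted(unknown)}")
    _validate_params(name, merged)
    return ChaoticMap(name, merged, native)


def _validate_params(name: str, p: dict) -> None:
    if name == "tent" and not 0.0 < p["beta"] < 1.0:
        raise ValueError("tent beta must be in (0, 1)")
    if name == "chebyshev" and p["phi"] < 2.0:
        raise ValueError("chebyshev order must be >= 2 for chaotic behaviour")
    if name == "sine" and not 0.0 < p["a"] <= 4.0:
        raise ValueError("sine parameter a must be in (0, 4]")
    if name == "singer" and not 0.9 < p["mu"] < 1.08:
        raise ValueError("singer mu must be in (0.9, 1.08)")
    if name == "logistic" and not 0.0 <= p["mu"] <= 4.0:
        raise ValueError("logistic mu must be in [0, 4]")
    if name == "cubic" and p["rho"] < 1.0:
        # the sub-unit parameter range collapses to the fixed point 0
        logger.warning("cubic rho=%s < 1 is non-chaotic (attracts to 0)", p["rho"])


def iterate_map(chaotic_map: ChaoticMap, z: float) -> float:
    """Apply one step of the map's recurrence to state ``z``.

    Raises ``ValueError`` when ``z`` lies outside the map's admissible
    domain (e.g. outside [0, 1] for the tent map, or exactly 0 for the
    iterative map, whose rule divides by the state).
    """
    name, p = chaotic_map.name, chaotic_map.params
    if name == "tent":
        _check_domain(z, 0.0, 1.0, name)
        beta = p["beta"]
        return z / beta if z < beta else (1.0 - z) / (1.0 - beta)
    if name == "chebyshev":
        _check_domain(z, -1.0, 1.0, name)
        return float(np.cos(p["phi"] * np.arccos(z)))
    if name == "circle":
        _check_domain(z, 0.0, 1.0, name)
        return float(np.mod(z + 0.2 - (0.5 / (2.0 * np.pi)) * np.sin(2.0 * np.pi * z), 1.0))
    if name == "iterative":
        if z == 0.0:
            raise ValueError("iterative map is undefined at z=0")
        if not -1.0 <= z <= 1.0:
            raise ValueError(f"iterative map state {z} outside [-1, 1]")
        return float(np.sin(p["a"] * np.pi / z))
    if name == "sine":
        _check_domain(z, 0.0, 1.0, name)
        return float((p["a"] / 4.0) * np.sin(np.pi * z))
    if name == "singer":
        _check_domain(z, 0.0, 1.0, name)
        return float(
            p["mu"] * (7.86 * z - 23.31 * z**2 + 28.75 * z**3 - 13.302875 * z**4)
        )
    if name == "sinusoidal":
        _check_domain(z, 0.0, 1.0, name)
        return float(p["a"] * z * z * np.sin(np.pi * z))
    if name == "logistic":
        _check_domain(z, 0.0, 1.0, name)
        return float(p["mu"] * z * (1.0 - z))
    if name == "cubic":
        _check_domain(z, 0.0, 1.0, name)
        return float(p["rho"] * z * (1.0 - z * z))
    raise AssertionError(name)


def _check_domain(z: float, lo: float, hi: float, name: str) -> None:
    if not lo <= z <= hi:
        raise ValueError(f"{name} map state {z} outside admissible domain [{lo}, {hi}]")


class ChaosStream:
    """Stateful iterator over a chaotic map, yielding values in [0, 1].

    The initial state is drawn uniformly from (0.01, 0.99) using the
    supplied RNG (unless ``z0`` is given).  Absorbing or inadmissible
    states — e.g. the logistic map landing exactly on 0 — are escaped by
    re-drawing the state, keeping long sequences non-degenerate.
    """

    def __init__(
        self,
        chaotic_map: ChaoticMap,
        rng: np.random.Generator,
        z0: Optional[float] = None,
    ) -> None:
        self.map = chaotic_map
        self._rng = rng
        self.z = float(z0) if z0 is not None else self._draw_state()

    def _draw_state(self) -> float:
        return float(self._rng.uniform(0.01, 0.99))

    def next_raw(self) -> float:
        """Advance the stream one step and return the raw (native) iterate."""
        try:
            z_new = iterate_map(self.map, self.z)
        except ValueError:
            z_new = self._draw_state()
        if abs(z_new) < 1e-12 or not np.isfinite(z_new):
            z_new = self._draw_state()  # escape absorbing states
        self.z = z_new
        return z_new

    def next(self) -> float:
        """Advance one step and return the iterate rescaled to [0, 1]."""
        z = self.next_raw()
        lo, hi = self.map.native_range
        if (lo, hi) == (0.0, 1.0):
            return min(max(z, 0.0), 1.0)
        return min(max((z - lo) / (hi - lo), 0.0), 1.0)

    def sequence(self, n: int) -> np.ndarray:
        """The next ``n`` normalized iterates as an array."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return np.array([self.next() for _ in range(n)])


def chaotic_sequence(stream: ChaosStream, n: int) -> np.ndarray:
    """Functional alias for :meth:`ChaosStream.sequence`."""
    return stream.sequence(n)


def chaos_to_domain(c: float, m_min: float, m_max: float) -> float:
    """Affinely map a [0, 1] chaos value into the interval [m_min, m_max]."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"chaos value {c} outside [0, 1]")
    if m_min > m_max:
        raise ValueError("m_min must be <= m_max")
    return m_min + c * (m_max - m_min)


def perturb(x_prime: np.ndarray, x_n: np.ndarray) -> np.ndarray:
    """Blend a solution with a chaos-derived point: the elementwise midpoint."""
    x_prime = np.asarray(x_prime, dtype=float)
    x_n = np.asarray(x_n, dtype=float)
    if x_prime.shape != x_n.shape:
        raise ValueError(f"shape mismatch: {x_prime.shape} vs {x_n.shape}")
    return (x_prime + x_n) / 2.0


def chaotic_init_population(
    chaotic_map: ChaoticMap,
    n_individuals: int,
    n_dims: int,
    lower_bound: float,
    upper_bound: float,
    seed=None,
) -> np.ndarray:
    """Seed an (N, D) position matrix from one long chaotic sequence.

    The sequence is iterated N*D times, normalized to [0, 1], and mapped
    affinely into [lower_bound, upper_bound].
    """
    if n_individuals < 1 or n_dims < 1:
        raise ValueError("population and dimension counts must be >= 1")
    if not lower_bound < upper_bound:
        raise ValueError("lower_bound must be < upper_bound")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stream = ChaosStream(chaotic_map, rng)
    values = stream.sequence(n_individuals * n_dims)
    return lower_bound + values.reshape(n_individuals, n_dims) * (upper_bound - lower_bound)
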