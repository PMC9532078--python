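"""Minimal dense feedforward network with sigmoid activations and MSE loss.

All trainable parameters live in a single flat vector (layer-major, weight
matrix then bias per layer) so a swarm optimizer can search them as one
box-constrained continuous problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["NetworkSpec", "sigmoid", "forward", "mse", "flatten", "unflatten"]


@dataclass(frozen=True)
class NetworkSpec:
    """Layer sizes, input first and output last; sigmoid on every layer."""

    layer_sizes: tuple[int, ...]

    def __init__(self, layer_sizes: Sequence[int]) -> None:
        sizes = tuple(int(s) for s in layer_sizes)
        if len(sizes) < 2:
            raise ValueError("need at least an input and an output layer")
        if any(s < 1 for s in sizes):
            raise ValueError("all layer sizes must be >= 1")
        object.__setattr__(self, "layer_sizes", sizes)

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    @property
    def weight_count(self) -> int:
        """Total parameters: (fan_in + 1) * fan_out per consecutive pair."""
        return sum(
            (fan_in + 1) * fan_out
            for fan_in, fan_out in zip(self.layer_sizes, self.layer_sizes[1:])
        )

    @classmethod
    def parse(cls, text: str) -> "NetworkSpec":
        """Parse an architecture string such as ``"26-16-16-1"``."""
        return cls([int(part) for part in text.split("-")])

    def __str__(self) -> str:
        return "-".join(str(s) for s in self.layer_sizes)


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def unflatten(vector: np.ndarray, spec: NetworkSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a flat parameter vector into per-layer (weights, bias) pairs.

    Weights for the layer mapping fan_in -> fan_out have shape
    (fan_in, fan_out); biases have shape (fan_out,).
    """
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size != spec.weight_count:
        raise ValueError(
            f"expected a flat vector of length {spec.weight_count}, got shape {vector.shape}"
        )
    layers = []
    offset = 0
    for fan_in, fan_out in zip(spec.layer_sizes, spec.layer_sizes[1:]):
        w = vector[offset : offset + fan_in * fan_out].reshape(fan_in, fan_out)
        offset += fan_in * fan_out
        b = vector[offset : offset + fan_out]
        offset += fan_out
        layers.append((w, b))
    return layers


def flatten(layers: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Inverse of :func:`unflatten`."""
    parts = []
    for w, b in layers:
        parts.append(np.asarray(w, dtype=float).ravel())
        parts.append(np.asarray(b, dtype=float).ravel())
    return np.concatenate(parts)


def forward(spec: NetworkSpec, weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Batch forward pass; returns the (n, n_outputs) activation matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns but the network expects {spec.n_inputs}"
        )
    h = X
    for w, b in unflatten(weights, spec):
        h = sigmoid(h @ w + b)
    return h


def mse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Mean squared error (1/m) * sum((O_k - A_k)^2) over all entries."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {actual.shape}")
    if predicted.size == 0:
        raise ValueError("mse of empty input is undefined")
    m = predicted.shape[0] if predicted.ndim > 0 else 1
    return float(np.sum((predicted - actual) ** 2) / m)
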