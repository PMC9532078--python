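"""Swarm-driven weight search for the feedforward classifier.

The flat weight vector is the optimizer's position; training MSE is the
fitness.  Global search (improved sparrow loop with the iterative chaotic
map by default) is optionally followed by local Adam refinement using
analytic backpropagation gradients; refinement is monitored so the reported
training MSE never increases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .chaos import make_map
from .network import NetworkSpec, forward, mse, sigmoid, unflatten, flatten
from .optimizer import SparrowConfig, run_cgssa

__all__ = ["TrainerConfig", "Model", "fitness", "train", "adam_refine", "mse_gradient"]


@dataclass(frozen=True)
class TrainerConfig:
    spec: NetworkSpec
    pop_size: int = 30
    max_iter: int = 1000
    weight_bound: float = 5.0
    map_name: str = "iterative"
    refine_epochs: int = 0
    learning_rate: float = 0.001
    standardize: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.weight_bound <= 0 or not np.isfinite(self.weight_bound):
            raise ValueError("weight search box must be finite and positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Model:
    """A trained network plus the feature standardization fitted on training data."""

    spec: NetworkSpec
    weights: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Scores in (0, 1) for the positive class, shape (n,)."""
        return forward(self.spec, self.weights, self.transform(X))[:, 0]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def to_json(self, path: Path) -> None:
        payload = {
            "layer_sizes": list(self.spec.layer_sizes),
            "weights": self.weights.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Path) -> "Model":
        payload = json.loads(Path(path).read_text())
        return cls(
            spec=NetworkSpec(payload["layer_sizes"]),
            weights=np.asarray(payload["weights"]),
            feature_mean=np.asarray(payload["feature_mean"]),
            feature_scale=np.asarray(payload["feature_scale"]),
        )


def fitness(
    weight_vector: np.ndarray, spec: NetworkSpec, X: np.ndarray, y: np.ndarray
) -> float:
    """Training MSE of the network parameterized by ``weight_vector``."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    return mse(forward(spec, weight_vector, X), y)


def _standardizer(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if not enabled:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns pass through
    return mean, scale


def train(
    X: np.ndarray, y: np.ndarray, cfg: TrainerConfig
) -> tuple[Model, np.ndarray]:
    """Fit the network to binary targets; returns the model and its MSE trace.

    The trace is the optimizer's best-so-far training MSE per iteration
    (non-increasing); Adam refinement, when enabled, can only lower the
    final training MSE (it is rolled back otherwise).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if X.shape[1] != cfg.spec.n_inputs:
        raise ValueError(
            f"data has {X.shape[1]} features but the network expects {cfg.spec.n_inputs}"
        )
    mean, scale = _standardizer(X, cfg.standardize)
    Xs = (X - mean) / scale

    opt_cfg = SparrowConfig(
        dim=cfg.spec.weight_count,
        lower_bound=-cfg.weight_bound,
        upper_bound=cfg.weight_bound,
        pop_size=cfg.pop_size,
        max_iter=cfg.max_iter,
        chaotic_map=make_map(cfg.map_name),
        seed=cfg.seed,
    )
    result = run_cgssa(lambda w: fitness(w, cfg.spec, Xs, y), opt_cfg)
    weights = result.best_position

    if cfg.refine_epochs > 0:
        refined = adam_refine(
            weights, cfg.spec, Xs, y, lr=cfg.learning_rate, epochs=cfg.refine_epochs
        )
        if fitness(refined, cfg.spec, Xs, y) <= result.best_fitness:
            weights = refined

    model = Model(spec=cfg.spec, weights=weights, feature_mean=mean, feature_scale=scale)
    return model, result.trace


def mse_gradient(
    weights: np.ndarray, spec: NetworkSpec, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Analytic gradient of the training MSE w.r.t. the flat weight vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    layers = unflatten(weights, spec)
    activations = [X]
    h = X
    for w, b in layers:
        h = sigmoid(h @ w + b)
        activations.append(h)
    m = X.shape[0]
    delta = (2.0 / m) * (activations[-1] - y)  # d MSE / d output
    grads: list[tuple[np.ndarray, np.ndarray]] = []
    for layer_idx in range(len(layers) - 1, -1, -1):
        w, _ = layers[layer_idx]
        a_out = activations[layer_idx + 1]
        a_in = activations[layer_idx]
        delta = delta * a_out * (1.0 - a_out)  # sigmoid derivative
        grads.append((a_in.T @ delta, delta.sum(axis=0)))
        if layer_idx > 0:
            delta = delta @ w.T
    grads.reverse()
    return flatten(grads)


def adam_refine(
    weights: np.ndarray,
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    lr: float = 0.001,
    epochs: int = 100,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> np.ndarray:
    """Full-batch Adam on the MSE objective, with best-seen early stopping.

    Returns the parameter vector with the lowest training MSE visited; with
    ``epochs=0`` the input weights are returned unchanged.
    """
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    w = np.asarray(weights, dtype=float).copy()
    if epochs == 0:
        return w
    y = np.asarray(y, dtype=float).reshape(-1)
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    best_w = w.copy()
    best_loss = fitness(w, spec, X, y)
    for t in range(1, epochs + 1):
        g = mse_gradient(w, spec, X, y)
        m = beta1 * m + (1.0 - beta1) * g
        v = beta2 * v + (1.0 - beta2) * g * g
        m_hat = m / (1.0 - beta1**t)
        v_hat = v / (1.0 - beta2**t)
        w = w - lr * m_hat / (np.sqrt(v_hat) + eps)
        loss = fitness(w, spec, X, y)
        if loss < best_loss:
            best_loss = loss
            best_w = w.copy()
    return best_w
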