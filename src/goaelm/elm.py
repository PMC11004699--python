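"""Extreme learning machine (ELM) with swarm-chosen hidden weights.

An ELM is a single-hidden-layer feedforward network whose hidden-layer
input weights ``W`` and biases ``b`` are fixed rather than trained; the
output weights ``beta`` are solved in closed form as the minimum-norm
least-squares solution ``beta = pinv(H) @ T`` where ``H`` is the hidden
output matrix and ``T`` the target matrix.

Here the hidden weights are not left random: they are encoded as a flat
agent vector and chosen by the amended grasshopper optimizer to minimize
the training sum of squared errors between the network scores and the
targets.  The closed-form ``beta`` is recomputed inside every fitness
evaluation, so the optimizer searches only over ``(W, b)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Tuple

import numpy as np

from .optimizers import (
    BoxBounds,
    OptimizationResult,
    OptimizerConfig,
    agoa_config,
    optimize,
)

__all__ = [
    "TrainingSet",
    "ELMParams",
    "ELMModel",
    "ACTIVATIONS",
    "hidden_output_matrix",
    "solve_output_weights",
    "predict",
    "elm_fitness",
    "encode_params",
    "decode_params",
    "train_elm_agoa",
    "train_elm_random",
    "save_model",
    "load_model",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
    "linear": lambda z: z,
}


@dataclass(frozen=True)
class TrainingSet:
    """Samples ``inputs`` (n x d) with one-hot targets ``labels`` (n x k)."""

    inputs: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.inputs, dtype=float)
        T = np.asarray(self.labels, dtype=float)
        if X.ndim != 2 or T.ndim != 2 or X.shape[0] != T.shape[0]:
            raise ValueError("inputs and labels must be 2-D with matching row counts")
        object.__setattr__(self, "inputs", X)
        object.__setattr__(self, "labels", T)

    @classmethod
    def from_class_labels(cls, X: np.ndarray, y: np.ndarray, n_classes: int = 2) -> "TrainingSet":
        y = np.asarray(y, dtype=int)
        T = np.zeros((y.size, n_classes))
        T[np.arange(y.size), y] = 1.0
        return cls(np.asarray(X, dtype=float), T)

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_features(self) -> int:
        return self.inputs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.labels.shape[1]

    @property
    def class_labels(self) -> np.ndarray:
        return np.argmax(self.labels, axis=1)


@dataclass(frozen=True)
class ELMParams:
    """Hidden-layer input weights (L_h x d), biases (L_h,), and activation."""

    input_weights: np.ndarray
    biases: np.ndarray
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        W = np.asarray(self.input_weights, dtype=float)
        b = np.asarray(self.biases, dtype=float)
        if W.ndim != 2 or b.ndim != 1 or W.shape[0] != b.size:
            raise ValueError("input_weights must be (L_h, d) and biases (L_h,)")
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
            raise ValueError("hidden parameters must be finite")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        object.__setattr__(self, "input_weights", W)
        object.__setattr__(self, "biases", b)

    @property
    def hidden_count(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


@dataclass(frozen=True)
class ELMModel:
    params: ELMParams
    output_weights: np.ndarray  # (L_h, k)

    def __post_init__(self) -> None:
        beta = np.asarray(self.output_weights, dtype=float)
        if beta.ndim != 2 or beta.shape[0] != self.params.hidden_count:
            raise ValueError("output_weights must be (L_h, k)")
        object.__setattr__(self, "output_weights", beta)


def hidden_output_matrix(inputs: np.ndarray, params: ELMParams) -> np.ndarray:
    """H[i, j] = activation(w_j . x_i + b_j), shape (n, L_h)."""
    X = np.asarray(inputs, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n_features:
        raise ValueError(
            f"inputs must be (n, {params.n_features}), got {X.shape}"
        )
    act = ACTIVATIONS[params.activation]
    return act(X @ params.input_weights.T + params.biases)


def solve_output_weights(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights beta = pinv(H) @ T."""
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T must have the same number of rows")
    return np.linalg.pinv(H) @ T


def predict(model: ELMModel, inputs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Return (predicted class indices, raw scores H @ beta).

    Ties in the scores resolve to the lowest class index.
    """
    H = hidden_output_matrix(inputs, model.params)
    scores = H @ model.output_weights
    return np.argmax(scores, axis=1), scores


def encode_params(params: ELMParams) -> np.ndarray:
    """Flatten (W, b) into an agent vector: row-major W then b."""
    return np.concatenate([params.input_weights.ravel(), params.biases])


def decode_params(
    vector: np.ndarray, hidden_count: int, n_features: int, activation: str = "sigmoid"
) -> ELMParams:
    """Inverse of :func:`encode_params`; errors on wrong length."""
    vector = np.asarray(vector, dtype=float)
    expected = hidden_count * n_features + hidden_count
    if vector.size != expected:
        raise ValueError(f"agent vector must have length {expected}, got {vector.size}")
    W = vector[: hidden_count * n_features].reshape(hidden_count, n_features)
    b = vector[hidden_count * n_features :]
    return ELMParams(W, b, activation)


def elm_fitness(
    agent_vector: np.ndarray,
    training: TrainingSet,
    hidden_count: int,
    activation: str = "sigmoid",
) -> float:
    """Training SSE of the ELM decoded from ``agent_vector``.

    Decodes (W, b), solves beta in closed form on the training set, and
    returns sum_k (D_k - H_k)^2 between targets and network scores.
    Non-finite results map to +inf so the optimizer can discard them.
    """
    params = decode_params(agent_vector, hidden_count, training.n_features, activation)
    H = hidden_output_matrix(training.inputs, params)
    beta = solve_output_weights(H, training.labels)
    sse = float(np.sum((training.labels - H @ beta) ** 2))
    return sse if np.isfinite(sse) else float("inf")


def _model_from_vector(
    vector: np.ndarray, training: TrainingSet, hidden_count: int, activation: str
) -> ELMModel:
    params = decode_params(vector, hidden_count, training.n_features, activation)
    H = hidden_output_matrix(training.inputs, params)
    return ELMModel(params, solve_output_weights(H, training.labels))


def train_elm_agoa(
    training: TrainingSet,
    hidden_count: int = 50,
    activation: str = "sigmoid",
    weight_bound: float = 1.0,
    optimizer_config: Optional[OptimizerConfig] = None,
) -> Tuple[ELMModel, OptimizationResult]:
    """Tune (W, b) with AGOA, minimizing training SSE; beta stays closed-form.

    The search box is [-weight_bound, weight_bound] per component of the
    flat agent vector of length ``hidden_count * d + hidden_count``.
    """
    if len(np.unique(training.class_labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if optimizer_config is None:
        optimizer_config = agoa_config()
    dim = hidden_count * training.n_features + hidden_count
    bounds = BoxBounds.cube(-weight_bound, weight_bound, dim)
    objective = lambda v: elm_fitness(v, training, hidden_count, activation)
    result = optimize(objective, bounds, optimizer_config)
    model = _model_from_vector(result.best_position, training, hidden_count, activation)
    return model, result


def train_elm_random(
    training: TrainingSet,
    hidden_count: int = 50,
    activation: str = "sigmoid",
    weight_bound: float = 1.0,
    seed: int = 0,
) -> ELMModel:
    """Plain ELM baseline: one random (W, b) draw, closed-form beta."""
    if len(np.unique(training.class_labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-weight_bound, weight_bound, size=(hidden_count, training.n_features))
    b = rng.uniform(-weight_bound, weight_bound, size=hidden_count)
    params = ELMParams(W, b, activation)
    H = hidden_output_matrix(training.inputs, params)
    return ELMModel(params, solve_output_weights(H, training.labels))


def save_model(model: ELMModel, stem: Path) -> None:
    """Write ``<stem>.json`` (metadata) and ``<stem>.npz`` (array sidecar)."""
    stem = Path(stem)
    meta = {
        "activation": model.params.activation,
        "hidden_count": model.params.hidden_count,
        "n_features": model.params.n_features,
        "n_classes": model.output_weights.shape[1],
        "arrays": stem.with_suffix(".npz").name,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(
        stem.with_suffix(".npz"),
        input_weights=model.params.input_weights,
        biases=model.params.biases,
        output_weights=model.output_weights,
    )


def load_model(stem: Path) -> ELMModel:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    arrays = np.load(stem.parent / meta["arrays"])
    params = ELMParams(
        arrays["input_weights"], arrays["biases"], meta["activation"]
    )
    return ELMModel(params, arrays["output_weights"])
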