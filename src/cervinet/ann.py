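"""Feed-forward regression network and Levenberg-Marquardt trainer.

The network maps the 18 z-scored kinematic predictors to a single linear
regression output (the predicted NFHAS change), through one or two hidden
layers of bounded sigmoidal (tanh) units.  Training minimizes squared
error with the Levenberg-Marquardt algorithm: damped Gauss-Newton steps
(J'J + lambda*I) delta = J'r, with the damping factor lambda decreased
after an accepted step and increased after a rejected one, interpolating
between gradient descent and Newton behaviour.

Both the analytic per-sample Jacobian and the trainer are implemented here
from first principles; scipy is used only for linear algebra.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "NetArchitecture",
    "NetModel",
    "TrainConfig",
    "init_model",
    "forward",
    "jacobian",
    "train_lm",
    "mse",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetArchitecture:
    """Layer sizes and activations of the regression network."""

    n_inputs: int = 18
    hidden_layers: tuple[int, ...] = (10,)
    n_outputs: int = 1
    hidden_activation: Literal["tanh", "logistic", "identity"] = "tanh"

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs != 1:
            raise ValueError("network must have >=1 input and exactly 1 output")
        # zero hidden layers = plain linear regression, kept as a degenerate
        # case for oracle checks; the architecture search uses 1 or 2
        if len(self.hidden_layers) > 2:
            raise ValueError("at most 2 hidden layers are supported")
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden widths must be >= 1")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_layers, self.n_outputs)

    @property
    def n_params(self) -> int:
        sizes = self.layer_sizes
        return sum((sizes[i] + 1) * sizes[i + 1] for i in range(len(sizes) - 1))


@dataclass
class NetModel:
    """Architecture plus per-layer weight matrices and bias vectors."""

    architecture: NetArchitecture
    weights: list[np.ndarray]  # weights[l]: (n_out_l, n_in_l)
    biases: list[np.ndarray]  # biases[l]: (n_out_l,)
    init_seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.architecture.layer_sizes
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l + 1], sizes[l]) or b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l} parameter shapes inconsistent with architecture")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError("parameters must be finite")

    def flatten(self) -> np.ndarray:
        """Parameter vector: per layer, weights row-major then biases."""
        return np.concatenate(
            [np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)]
        )

    def with_params(self, theta: np.ndarray) -> "NetModel":
        sizes = self.architecture.layer_sizes
        weights, biases, k = [], [], 0
        for l in range(len(sizes) - 1):
            n_out, n_in = sizes[l + 1], sizes[l]
            weights.append(theta[k : k + n_out * n_in].reshape(n_out, n_in).copy())
            k += n_out * n_in
            biases.append(theta[k : k + n_out].copy())
            k += n_out
        return NetModel(self.architecture, weights, biases, self.init_seed)


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt damping schedule and stop criteria."""

    lambda_init: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    lambda_max: float = 1e10
    max_epochs: int = 1000
    gradient_tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_init <= 0 or self.lambda_up <= 1 or not 0 < self.lambda_down < 1:
            raise ValueError("invalid damping schedule")


def _activation(name: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Activation value and elementwise derivative."""
    if name == "tanh":
        a = np.tanh(x)
        return a, 1.0 - a * a
    if name == "logistic":
        a = 1.0 / (1.0 + np.exp(-x))
        return a, a * (1.0 - a)
    if name == "identity":
        return x, np.ones_like(x)
    raise ValueError(f"unknown activation {name!r}")


def init_model(
    architecture: NetArchitecture,
    seed: int = 0,
    scheme: Literal["uniform", "nguyen-widrow"] = "uniform",
) -> NetModel:
    """Random initialization: uniform in [-0.5, 0.5] (default) or Nguyen-Widrow."""
    rng = np.random.default_rng(seed)
    sizes = architecture.layer_sizes
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        n_in, n_out = sizes[l], sizes[l + 1]
        w = rng.uniform(-0.5, 0.5, size=(n_out, n_in))
        b = rng.uniform(-0.5, 0.5, size=n_out)
        if scheme == "nguyen-widrow" and l < len(sizes) - 2:
            beta = 0.7 * n_out ** (1.0 / n_in)
            norms = np.linalg.norm(w, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            w = beta * w / norms
            b = rng.uniform(-beta, beta, size=n_out)
        weights.append(w)
        biases.append(b)
    return NetModel(architecture, weights, biases, init_seed=seed)


def _forward_pass(model: NetModel, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Batch forward pass; returns (outputs, activations per layer, derivatives)."""
    act_name = model.architecture.hidden_activation
    n_hidden = len(model.architecture.hidden_layers)
    a = x
    activations = [a]
    derivs: list[np.ndarray] = []
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w.T + b
        if l < n_hidden:
            a, d = _activation(act_name, z)
        else:  # linear output layer
            a, d = z, np.ones_like(z)
        activations.append(a)
        derivs.append(d)
    return a[:, 0], activations, derivs


def forward(model: NetModel, features: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """Network output for one feature vector or a batch (rows = samples)."""
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.architecture.n_inputs:
        raise ValueError(
            f"expected {model.architecture.n_inputs} features, got {x.shape[1]}"
        )
    y, _, _ = _forward_pass(model, x)
    return float(y[0]) if single else y


def jacobian(model: NetModel, features: np.ndarray) -> np.ndarray:
    """Per-sample derivatives of the output w.r.t. the flattened parameters.

    Rows are samples, columns follow the ordering of ``NetModel.flatten``
    (per layer: weights row-major, then biases).  Computed by reverse-mode
    accumulation of the scalar output.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.architecture.n_inputs:
        raise ValueError("feature width does not match the network input layer")
    n = x.shape[0]
    y, activations, derivs = _forward_pass(model, x)
    n_layers = len(model.weights)
    # delta[l][i, j] = d y_i / d z_j at layer l
    deltas: list[np.ndarray] = [np.empty(0)] * n_layers
    deltas[n_layers - 1] = derivs[n_layers - 1]  # output layer: (n, 1) of ones
    for l in range(n_layers - 2, -1, -1):
        deltas[l] = (deltas[l + 1] @ model.weights[l + 1]) * derivs[l]
    cols = []
    for l in range(n_layers):
        a_prev = activations[l]  # (n, n_in)
        d = deltas[l]  # (n, n_out)
        # d y / d W[j, k] = delta_j * a_prev_k, flattened row-major
        cols.append((d[:, :, None] * a_prev[:, None, :]).reshape(n, -1))
        cols.append(d)  # d y / d b_j
    J = np.concatenate(cols, axis=1)
    assert J.shape == (n, model.architecture.n_params)
    return J


def mse(predictions: Sequence[float], targets: Sequence[float]) -> float:
    """Mean squared error between two equal-length vectors."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and targets must have equal nonzero length")
    return float(np.mean((p - t) ** 2))


def train_lm(
    model: NetModel,
    features: np.ndarray,
    targets: Sequence[float],
    config: TrainConfig | None = None,
) -> tuple[NetModel, list[float]]:
    """Train by Levenberg-Marquardt; returns (trained model, per-epoch MSE history).

    Each epoch solves (J'J + lambda*I) delta = J'r for the residuals
    r = t - y.  A step is accepted if it lowers the training MSE (then
    lambda shrinks); otherwise it is rejected and retried with a larger
    lambda.  Training stops on max_epochs, on an infinity-norm gradient
    below gradient_tol, or when lambda exceeds lambda_max.  The history
    records the MSE after each epoch and is non-increasing.
    """
    if config is None:
        config = TrainConfig()
    x = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.asarray(targets, dtype=float)
    if x.shape[0] != t.size or t.size == 0:
        raise ValueError("need >= 1 sample with matching targets")
    if not np.isfinite(t).all():
        raise ValueError("targets must be finite")

    theta = model.flatten()
    current = model
    lam = config.lambda_init
    y = forward(current, x)
    current_mse = mse(y, t)
    history = [current_mse]
    n_params = theta.size

    for _ in range(config.max_epochs):
        J = jacobian(current, x)
        r = t - forward(current, x)
        g = J.T @ r
        if np.max(np.abs(g)) < config.gradient_tol:
            break
        JtJ = J.T @ J
        accepted = False
        while lam <= config.lambda_max:
            A = JtJ + lam * np.eye(n_params)
            try:
                delta = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                lam *= config.lambda_up  # singular at small lambda: damp harder
                continue
            trial_theta = theta + delta
            trial = current.with_params(trial_theta)
            trial_mse = mse(forward(trial, x), t)
            if np.isfinite(trial_mse) and trial_mse < current_mse:
                theta, current, current_mse = trial_theta, trial, trial_mse
                lam = max(lam * config.lambda_down, np.finfo(float).tiny)
                accepted = True
                break
            lam *= config.lambda_up
        history.append(current_mse)
        if not accepted:  # lambda exhausted
            break
    return current, history


# ---------------------------------------------------------------------------
# JSON serialization for exact reload

def save_model(
    model: NetModel,
    path: str | Path,
    *,
    train_config: TrainConfig | None = None,
    zscore_params: dict | None = None,
) -> None:
    payload = {
        "architecture": asdict(model.architecture),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "init_seed": model.init_seed,
        "train_config": asdict(train_config) if train_config else None,
        "zscore_params": zscore_params,
    }
    payload["architecture"]["hidden_layers"] = list(
        payload["architecture"]["hidden_layers"]
    )
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> NetModel:
    payload = json.loads(Path(path).read_text())
    arch_d = dict(payload["architecture"])
    arch_d["hidden_layers"] = tuple(arch_d["hidden_layers"])
    arch = NetArchitecture(**arch_d)
    return NetModel(
        architecture=arch,
        weights=[np.array(w, dtype=float) for w in payload["weights"]],
        biases=[np.array(b, dtype=float) for b in payload["biases"]],
        init_seed=int(payload["init_seed"]),
    )
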