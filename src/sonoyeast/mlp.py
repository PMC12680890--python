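"""Compact fully connected networks trained with full-batch L-BFGS.

Architecture shared by every modeling approach: two hidden ReLU layers with
five and three neurons, Glorot-uniform initialization, L2 penalty
(lambda = 0.001) on weights (not biases), and a task-specific head — a
single linear neuron minimizing MSE for regression, or a three-way softmax
minimizing categorical cross-entropy for strain classification.

Training is deterministic: the full batch is handed to L-BFGS, gradients
are analytic (backpropagation, verified against finite differences in the
test suite), and early stopping watches an inner validation split held out
from the training rows before optimization, with a patience counted in
L-BFGS iterations (the natural "epoch" of a full-batch optimizer).  The
returned weights are those of the best-validation iterate.

Two interfaces are exposed: a functional one (``init_glorot``, ``forward``,
``loss``, ``gradient``, ``train_lbfgs``) and scikit-learn estimators
(:class:`CompactMLPRegressor`, :class:`CompactMLPClassifier`) that compose
with :class:`~sklearn.pipeline.Pipeline` and ``clone``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

__all__ = [
    "NetworkWeights",
    "TrainingTrace",
    "TrainedNetwork",
    "TrainingDivergedError",
    "init_glorot",
    "forward",
    "loss",
    "gradient",
    "train_lbfgs",
    "CompactMLPRegressor",
    "CompactMLPClassifier",
]

Task = Literal["regression", "classification"]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during optimization."""

    def __init__(self, message: str, trace: "TrainingTrace | None" = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class NetworkWeights:
    """Weight matrices and bias vectors, input side first."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    def pack(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in (*self.weights, *self.biases)])

    @classmethod
    def unpack(cls, flat: np.ndarray, sizes: Sequence[int]) -> "NetworkWeights":
        weights, biases, k = [], [], 0
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            weights.append(flat[k : k + fan_in * fan_out].reshape(fan_in, fan_out))
            k += fan_in * fan_out
        for fan_out in sizes[1:]:
            biases.append(flat[k : k + fan_out])
            k += fan_out
        return cls(weights=weights, biases=biases)

    def squared_norm(self) -> float:
        """Sum of squared weight entries (biases excluded, as in the penalty)."""
        return float(sum(np.sum(w**2) for w in self.weights))


@dataclass
class TrainingTrace:
    """Per-iteration record of the optimization."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_iteration: int = 0
    n_iterations: int = 0
    stop_reason: str = ""


@dataclass
class TrainedNetwork:
    """Outcome of :func:`train_lbfgs`: best-validation weights plus trace."""

    weights: NetworkWeights
    task: Task
    trace: TrainingTrace


def init_glorot(layer_sizes: Sequence[int], rng: np.random.Generator) -> NetworkWeights:
    """Glorot-uniform weights, U(+-sqrt(6/(fan_in+fan_out))); zero biases."""
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkWeights(weights=weights, biases=biases)


def _affine_chain(net: NetworkWeights, X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Pre-activations z_l and post-ReLU activations a_l for hidden layers."""
    zs, acts = [], [X]
    for l, (W, b) in enumerate(zip(net.weights, net.biases)):
        z = acts[-1] @ W + b
        zs.append(z)
        if l < len(net.weights) - 1:
            acts.append(np.maximum(z, 0.0))
        else:
            acts.append(z)  # linear head; softmax applied by the caller
    return zs, acts


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def forward(net: NetworkWeights, X: np.ndarray, task: Task = "regression") -> np.ndarray:
    """Network output: (n,) predictions or (n, K) softmax probabilities."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"X must be 2-D with {net.layer_sizes[0]} columns, got shape {X.shape}"
        )
    _, acts = _affine_chain(net, X)
    out = acts[-1]
    if task == "classification":
        return _softmax(out)
    return out[:, 0]


def _data_loss(net: NetworkWeights, X: np.ndarray, y: np.ndarray, task: Task) -> float:
    _, acts = _affine_chain(net, X)
    out = acts[-1]
    n = X.shape[0]
    if task == "regression":
        return float(np.mean((out[:, 0] - y) ** 2))
    # stable mean cross-entropy of the softmax head
    shifted = out - out.max(axis=1, keepdims=True)
    log_z = np.log(np.sum(np.exp(shifted), axis=1))
    log_p = shifted[np.arange(n), y.astype(int)] - log_z
    return float(-np.mean(log_p))


def loss(net: NetworkWeights, X: np.ndarray, y: np.ndarray, l2: float, task: Task = "regression") -> float:
    """Data loss (MSE or cross-entropy) plus ``l2 * sum ||W||^2``."""
    return _data_loss(net, np.asarray(X, float), np.asarray(y), task) + l2 * net.squared_norm()


def gradient(net: NetworkWeights, X: np.ndarray, y: np.ndarray, l2: float, task: Task = "regression") -> NetworkWeights:
    """Analytic gradient of :func:`loss` via backpropagation.

    The ReLU subgradient at exactly zero is taken as zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    zs, acts = _affine_chain(net, X)
    out = acts[-1]
    if task == "regression":
        delta = np.zeros_like(out)
        delta[:, 0] = 2.0 * (out[:, 0] - y) / n
    else:
        probs = _softmax(out)
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y.astype(int)] = 1.0
        delta = (probs - onehot) / n
    g_w = [np.empty(0)] * len(net.weights)
    g_b = [np.empty(0)] * len(net.biases)
    for l in range(len(net.weights) - 1, -1, -1):
        g_w[l] = acts[l].T @ delta + 2.0 * l2 * net.weights[l]
        g_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ net.weights[l].T) * (zs[l - 1] > 0)
    return NetworkWeights(weights=g_w, biases=g_b)


def train_lbfgs(
    X: np.ndarray,
    y: np.ndarray,
    *,
    task: Task = "regression",
    hidden_layer_sizes: Sequence[int] = (5, 3),
    n_outputs: int | None = None,
    l2: float = 0.001,
    patience: int = 6,
    max_iter: int = 500,
    validation_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
    initial_weights: NetworkWeights | None = None,
) -> TrainedNetwork:
    """Full-batch L-BFGS fit with iteration-level early stopping.

    A fraction of the rows is held out before optimization; after every
    L-BFGS iteration the candidate weights are scored on it, and training
    stops when the validation loss has not improved for ``patience``
    consecutive iterations (or at ``max_iter``).  The best-validation
    iterate is returned.  L-BFGS line-search and convergence tolerances are
    the scipy defaults.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n = X.shape[0]
    if n < 10:
        raise ValueError("training requires at least 10 rows")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    rng = rng or np.random.default_rng()

    if task == "classification":
        n_out = n_outputs or int(np.max(y)) + 1
    else:
        n_out = 1
    sizes = (X.shape[1], *hidden_layer_sizes, n_out)

    # inner validation split, held out before the optimizer sees anything
    n_val = max(1, int(round(validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    X_fit, y_fit = X[fit_idx], y[fit_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    net0 = initial_weights or init_glorot(sizes, rng)
    x0 = net0.pack()
    trace = TrainingTrace()

    def objective(flat: np.ndarray) -> tuple[float, np.ndarray]:
        net = NetworkWeights.unpack(flat, sizes)
        value = loss(net, X_fit, y_fit, l2, task)
        if not np.isfinite(value):
            raise TrainingDivergedError("non-finite training loss", trace)
        return value, gradient(net, X_fit, y_fit, l2, task).pack()

    def val_loss_of(flat: np.ndarray) -> float:
        return loss(NetworkWeights.unpack(flat, sizes), X_val, y_val, l2, task)

    best = {"val": val_loss_of(x0), "x": x0.copy(), "iter": 0}
    stall = 0

    def callback(xk: np.ndarray) -> None:
        nonlocal stall
        trace.n_iterations += 1
        v = val_loss_of(xk)
        trace.train_loss.append(objective(xk)[0])
        trace.val_loss.append(v)
        if v < best["val"]:
            best.update(val=v, x=xk.copy(), iter=trace.n_iterations)
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                raise StopIteration

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter},
    )
    if res.status == 99:
        trace.stop_reason = "early_stopping"
    elif trace.n_iterations >= max_iter:
        trace.stop_reason = "max_iter"
    else:
        trace.stop_reason = "converged"
    trace.best_iteration = best["iter"]
    return TrainedNetwork(
        weights=NetworkWeights.unpack(best["x"], sizes),
        task=task,
        trace=trace,
    )


class _BaseCompactMLP(BaseEstimator):
    """Shared scikit-learn plumbing for the two heads."""

    _task: Task = "regression"

    def __init__(
        self,
        hidden_layer_sizes=(5, 3),
        alpha=0.001,
        patience=6,
        max_iter=500,
        validation_fraction=0.1,
        random_state=None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.patience = patience
        self.max_iter = max_iter
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _fit_network(self, X, y, n_outputs=None):
        rng = np.random.default_rng(self.random_state)
        fitted = train_lbfgs(
            X,
            y,
            task=self._task,
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            n_outputs=n_outputs,
            l2=self.alpha,
            patience=self.patience,
            max_iter=self.max_iter,
            validation_fraction=self.validation_fraction,
            rng=rng,
        )
        self.network_ = fitted.weights
        self.coefs_ = fitted.weights.weights
        self.intercepts_ = fitted.weights.biases
        self.loss_curve_ = fitted.trace.train_loss
        self.validation_curve_ = fitted.trace.val_loss
        self.n_iter_ = fitted.trace.n_iterations
        self.best_iteration_ = fitted.trace.best_iteration
        self.stop_reason_ = fitted.trace.stop_reason
        self.n_features_in_ = X.shape[1]
        return self

    def _check_is_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def _weights_payload(self) -> dict:
        return {
            "layer_sizes": list(self.network_.layer_sizes),
            "weights": [w.tolist() for w in self.network_.weights],
            "biases": [b.tolist() for b in self.network_.biases],
        }

    def _load_weights_payload(self, payload: dict) -> None:
        self.network_ = NetworkWeights(
            weights=[np.asarray(w, float) for w in payload["weights"]],
            biases=[np.asarray(b, float) for b in payload["biases"]],
        )
        self.coefs_ = self.network_.weights
        self.intercepts_ = self.network_.biases
        self.n_features_in_ = self.network_.layer_sizes[0]


class CompactMLPRegressor(RegressorMixin, _BaseCompactMLP):
    """Single-output ReLU network for cell-count regression.

    ``target_scale`` divides the targets before optimization and multiplies
    predictions back, keeping the MSE well-scaled when counts are given in
    cells/mL (use ``target_scale=1e6`` to optimize in 10^6 cells/mL).
    """

    _task: Task = "regression"

    def __init__(
        self,
        hidden_layer_sizes=(5, 3),
        alpha=0.001,
        patience=6,
        max_iter=500,
        validation_fraction=0.1,
        target_scale=1.0,
        random_state=None,
    ):
        super().__init__(
            hidden_layer_sizes=hidden_layer_sizes,
            alpha=alpha,
            patience=patience,
            max_iter=max_iter,
            validation_fraction=validation_fraction,
            random_state=random_state,
        )
        self.target_scale = target_scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of rows")
        return self._fit_network(X, y / self.target_scale)

    def predict(self, X):
        self._check_is_fitted()
        return forward(self.network_, np.asarray(X, float), "regression") * self.target_scale

    def to_dict(self) -> dict:
        self._check_is_fitted()
        return {"task": "regression", "params": self.get_params(), "network": self._weights_payload()}

    @classmethod
    def from_dict(cls, payload: dict) -> "CompactMLPRegressor":
        est = cls(**payload["params"])
        est._load_weights_payload(payload["network"])
        return est


class CompactMLPClassifier(ClassifierMixin, _BaseCompactMLP):
    """Softmax-head ReLU network for strain classification."""

    _task: Task = "classification"

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of rows")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("classification needs at least two classes")
        return self._fit_network(X, y_idx, n_outputs=len(self.classes_))

    def predict_proba(self, X):
        self._check_is_fitted()
        return forward(self.network_, np.asarray(X, float), "classification")

    def predict(self, X):
        # np.argmax resolves exact probability ties to the earliest class
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def to_dict(self) -> dict:
        self._check_is_fitted()
        return {
            "task": "classification",
            "params": self.get_params(),
            "classes": [c.item() if hasattr(c, "item") else c for c in self.classes_],
            "network": self._weights_payload(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CompactMLPClassifier":
        est = cls(**payload["params"])
        est._load_weights_payload(payload["network"])
        est.classes_ = np.asarray(payload["classes"])
        return est
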