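"""Multiclass softmax (multinomial logistic) regression by gradient ascent.

The model assigns sample ``x`` the class probabilities

    p(y = k | x; w) = exp(w_k' x) / sum_j exp(w_j' x),

with one weight vector per class (bias absorbed as an appended constant
column).  Fitting maximizes the L2-penalized mean log-likelihood

    J(w) = (1/m) sum_i log p(y_i | x_i; w) - (lambda/2) ||w||^2

by full-batch gradient ascent from ``w = 0``:

    grad_j J = (1/m) sum_i x_i (1[y_i = j] - p(y_i = j | x_i)) - lambda w_j.

All probability evaluations subtract the row-wise maximum score before
exponentiating; this leaves the probabilities mathematically unchanged and
prevents overflow.  The bias column is excluded from nothing here — the
penalty is applied to the full weight matrix, matching the simple penalized
update the model family is defined with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..containers import FeatureTable, ProbabilityMatrix

__all__ = [
    "SoftmaxModel",
    "fit_softmax",
    "softmax_probabilities",
    "softmax_log_likelihood",
    "softmax_gradient",
    "softmax_objective",
]


@dataclass
class SoftmaxModel:
    """Fitted softmax-regression weights plus the training configuration.

    ``weights`` is ``NC x (d + 1)``; the last column multiplies the
    appended bias constant 1.
    """

    weights: np.ndarray
    class_labels: np.ndarray
    learning_rate: float = 0.1
    l2_strength: float = 1e-4
    n_iterations: int = 500
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.class_labels = np.asarray(self.class_labels, dtype=np.int64)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-dimensional")
        if self.weights.shape[0] != self.class_labels.shape[0]:
            raise ValueError("one weight row per class required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_features(self) -> int:
        return self.weights.shape[1] - 1


def _with_bias(features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("features must be 2-dimensional")
    return np.hstack([x, np.ones((x.shape[0], 1))])


def _features_of(data) -> np.ndarray:
    return data.features if isinstance(data, FeatureTable) else np.asarray(data)


def _stable_probabilities(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _check_dim(model: SoftmaxModel, xb: np.ndarray) -> None:
    if xb.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"feature dimension {xb.shape[1] - 1} does not match model "
            f"dimension {model.n_features}"
        )


def softmax_probabilities(model: SoftmaxModel, features) -> ProbabilityMatrix:
    """Class-probability matrix for ``features`` (without bias column)."""
    xb = _with_bias(_features_of(features))
    _check_dim(model, xb)
    probs = _stable_probabilities(xb @ model.weights.T)
    return ProbabilityMatrix(values=probs, class_labels=model.class_labels)


def _one_hot(labels: np.ndarray, class_labels: np.ndarray) -> np.ndarray:
    index = {int(c): j for j, c in enumerate(class_labels)}
    cols = np.fromiter((index[int(v)] for v in labels), dtype=np.int64)
    y = np.zeros((labels.shape[0], class_labels.shape[0]))
    y[np.arange(labels.shape[0]), cols] = 1.0
    return y


def softmax_log_likelihood(model: SoftmaxModel, table: FeatureTable) -> float:
    """Unpenalized log-likelihood ``sum_i log p(y_i | x_i; w)``."""
    labels = table.require_labels()
    probs = softmax_probabilities(model, table).values
    y = _one_hot(labels, model.class_labels)
    # Clip avoids -inf only for exactly-zero probabilities (separable data).
    return float(np.sum(y * np.log(np.clip(probs, 1e-300, None))))


def softmax_objective(model: SoftmaxModel, table: FeatureTable) -> float:
    """The fitted objective: mean log-likelihood minus the L2 penalty."""
    m = table.n_samples
    penalty = 0.5 * model.l2_strength * float(np.sum(model.weights**2))
    return softmax_log_likelihood(model, table) / m - penalty


def softmax_gradient(model: SoftmaxModel, table: FeatureTable) -> np.ndarray:
    """Ascent gradient of the penalized objective, shape ``NC x (d + 1)``."""
    labels = table.require_labels()
    xb = _with_bias(table.features)
    _check_dim(model, xb)
    probs = _stable_probabilities(xb @ model.weights.T)
    y = _one_hot(labels, model.class_labels)
    m = xb.shape[0]
    return (y - probs).T @ xb / m - model.l2_strength * model.weights


def fit_softmax(
    table: FeatureTable,
    learning_rate: float = 0.1,
    l2_strength: float = 1e-4,
    n_iterations: int = 500,
    seed: int | None = None,
    class_labels: np.ndarray | None = None,
) -> SoftmaxModel:
    """Fit by full-batch gradient ascent from all-zero weights.

    The update is ``w <- w + learning_rate * grad`` with the penalized
    ascent gradient above.  The optimization is deterministic; ``seed`` is
    accepted only for interface uniformity with the stochastic learners.
    ``objective_trace[t]`` records the objective *after* ``t`` updates
    (entry 0 is the all-zero starting point, so a zero-iteration fit
    predicts the uniform distribution).
    """
    labels = table.require_labels()
    if class_labels is None:
        class_labels = table.class_labels
    class_labels = np.asarray(class_labels, dtype=np.int64)
    if n_iterations < 0:
        raise ValueError("n_iterations must be non-negative")
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")

    xb = _with_bias(table.features)
    y = _one_hot(labels, class_labels)
    m = xb.shape[0]
    w = np.zeros((class_labels.shape[0], xb.shape[1]))
    trace = np.empty(n_iterations + 1)

    for t in range(n_iterations + 1):
        probs = _stable_probabilities(xb @ w.T)
        ll = float(np.sum(y * np.log(np.clip(probs, 1e-300, None))))
        trace[t] = ll / m - 0.5 * l2_strength * float(np.sum(w**2))
        if not np.isfinite(trace[t]):
            raise FloatingPointError(
                "softmax objective became non-finite; try a smaller "
                "learning_rate"
            )
        if t == n_iterations:
            break
        grad = (y - probs).T @ xb / m - l2_strength * w
        w = w + learning_rate * grad

    return SoftmaxModel(
        weights=w,
        class_labels=class_labels,
        learning_rate=learning_rate,
        l2_strength=l2_strength,
        n_iterations=n_iterations,
        objective_trace=trace,
    )
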