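"""Feed-forward weight prediction: the MLP regressor, dataset splitting and
the four evaluation metrics.

The network is a fully connected perceptron with layer sizes
``[D, 5, 4, 4, 1]`` — rectifier (``max(0, x)``) activations on the three
hidden layers, a linear output — trained by mini-batch gradient descent
with the adaptive-moment (Adam) update (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on
the mean-squared-error loss for 300 epochs at batch size 10 and learning
rate 0.01.  The parameter count is ``5·D + 54`` for input dimension D.

Everything is seeded: initialization (uniform fan-in) and the per-epoch
batch shuffle derive from ``random_state``, so the full split → train →
evaluate pipeline is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InvalidParameterError, TrainingDivergedError

__all__ = [
    "SplitSpec",
    "split_dataset",
    "EvaluationReport",
    "evaluate",
    "WeightMLPRegressor",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation fractions (must sum to 1) and the shuffle seed."""

    train: float = 0.70
    test: float = 0.15
    validation: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.train, self.test, self.validation) < 0:
            raise InvalidParameterError("split fractions must be non-negative")
        if not np.isclose(self.train + self.test + self.validation, 1.0):
            raise InvalidParameterError("split fractions must sum to 1")


def split_dataset(table: pd.DataFrame, spec: SplitSpec = SplitSpec()):
    """Shuffled 70:15:15 partition; remainder rows go to the training set.

    Returns ``(train, test, validation)`` row subsets; the three parts are
    disjoint and cover the table.  Deterministic per seed.
    """
    n = len(table)
    if n == 0:
        raise InvalidParameterError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_test = int(np.floor(spec.test * n))
    n_val = int(np.floor(spec.validation * n))
    test_idx = order[:n_test]
    val_idx = order[n_test : n_test + n_val]
    train_idx = order[n_test + n_val :]
    return (
        table.iloc[train_idx].reset_index(drop=True),
        table.iloc[test_idx].reset_index(drop=True),
        table.iloc[val_idx].reset_index(drop=True),
    )


@dataclass(frozen=True)
class EvaluationReport:
    """MSE (kg²), RMSE (kg), MAE (kg), MAPE (fraction) over n predictions."""

    mse: float
    rmse: float
    mae: float
    mape: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mse": float(self.mse),
            "rmse": float(self.rmse),
            "mae": float(self.mae),
            "mape": float(self.mape),
            "n": int(self.n),
        }


def evaluate(actual, predicted) -> EvaluationReport:
    """MSE, RMSE, MAE and MAPE between actual and predicted weights.

    MAPE is reported as a fraction (0.04 = 4 %); it is undefined when any
    actual value is zero.
    """
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.shape != p.shape or len(a) < 1:
        raise InvalidParameterError("actual and predicted must be equal-length, non-empty")
    if np.any(a == 0):
        raise InvalidParameterError("MAPE undefined: an actual value is zero")
    err = a - p
    mse = float(np.mean(err**2))
    return EvaluationReport(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(err))),
        mape=float(np.mean(np.abs(err / a))),
        n=len(a),
    )


class WeightMLPRegressor(BaseEstimator, RegressorMixin):
    """Fully connected [D, *hidden_layer_sizes, 1] regressor with rectifier
    hidden activations, trained by seeded mini-batch Adam on MSE loss.

    Fitted attributes: ``coefs_`` / ``intercepts_`` (per layer),
    ``loss_curve_`` (training MSE per epoch), ``validation_curve_`` (if
    validation data was supplied), ``n_parameters_``.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (5, 4, 4),
        learning_rate: float = 0.01,
        epochs: int = 300,
        batch_size: int = 10,
        beta_1: float = 0.9,
        beta_2: float = 0.999,
        epsilon: float = 1e-8,
        shuffle: bool = True,
        n_restarts: int = 4,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.beta_1 = beta_1
        self.beta_2 = beta_2
        self.epsilon = epsilon
        self.shuffle = shuffle
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _initialize(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = [n_features, *self.hidden_layer_sizes, 1]
        if min(sizes) < 1:
            raise InvalidParameterError("all layer sizes must be positive")
        self.coefs_, self.intercepts_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.coefs_.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
            self.intercepts_.append(rng.uniform(-bound, bound, fan_out))
        self.n_parameters_ = sum(w.size + b.size for w, b in zip(self.coefs_, self.intercepts_))

    def _forward(self, x: np.ndarray, keep: bool = False):
        activations = [x]
        a = x
        for layer, (w, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = a @ w + b
            a = np.maximum(z, 0.0) if layer < len(self.coefs_) - 1 else z
            activations.append(a)
        return (activations if keep else a)

    def _batch_step(self, xb, yb, adam_state, t):
        acts = self._forward(xb, keep=True)
        pred = acts[-1][:, 0]
        m = len(yb)
        delta = (2.0 / m) * (pred - yb)[:, None]  # dL/dz at the linear output
        grads_w, grads_b = [], []
        for layer in range(len(self.coefs_) - 1, -1, -1):
            a_prev = acts[layer]
            grads_w.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.coefs_[layer].T) * (acts[layer] > 0)
        grads_w.reverse()
        grads_b.reverse()

        b1, b2, eps, lr = self.beta_1, self.beta_2, self.epsilon, self.learning_rate
        corr1 = 1.0 - b1**t
        corr2 = 1.0 - b2**t
        for params, grads, state in (
            (self.coefs_, grads_w, adam_state[0]),
            (self.intercepts_, grads_b, adam_state[1]),
        ):
            for i, g in enumerate(grads):
                m1, m2 = state[i]
                m1 *= b1
                m1 += (1 - b1) * g
                m2 *= b2
                m2 += (1 - b2) * g * g
                params[i] -= lr * (m1 / corr1) / (np.sqrt(m2 / corr2) + eps)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, validation_data: tuple | None = None):
        """Train the network.

        Optimizing this very small rectifier network from raw-scale inputs
        occasionally collapses onto the constant predictor or a mediocre
        local optimum (an all-dead hidden layer early in the violent
        initial transient; the same attractors are reachable with
        sklearn's MLPRegressor under the identical protocol).  Training is
        therefore multi-start: an attempt is accepted once it explains at
        least 85% of the training-target variance, otherwise it is
        re-initialized with the next seeded draw, up to ``n_restarts``
        times, and the attempt with the lowest final training MSE is kept.
        ``n_restarts_used_`` records how many re-initializations ran.
        """
        x = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float).ravel()
        if x.ndim != 2 or len(x) != len(yv) or len(x) == 0:
            raise InvalidParameterError("X must be (n, d) with matching non-empty y")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise InvalidParameterError("invalid epochs/batch_size/learning_rate")
        rng = np.random.default_rng(self.random_state)
        stall_level = 0.15 * float(np.var(yv)) if len(yv) > 1 else np.inf
        best = None
        for attempt in range(max(int(self.n_restarts), 0) + 1):
            self._fit_once(x, yv, validation_data, rng)
            final = self.loss_curve_[-1] if self.loss_curve_ else 0.0
            state = (
                final, self.coefs_, self.intercepts_,
                self.loss_curve_, self.validation_curve_,
            )
            if best is None or final < best[0]:
                best = state
            if self.epochs == 0 or final < stall_level:
                break
        (_, self.coefs_, self.intercepts_,
         self.loss_curve_, self.validation_curve_) = best
        self.n_restarts_used_ = attempt
        return self

    def _fit_once(self, x, yv, validation_data, rng):
        self.n_features_in_ = x.shape[1]
        self._initialize(x.shape[1], rng)

        adam_state = (
            [(np.zeros_like(w), np.zeros_like(w)) for w in self.coefs_],
            [(np.zeros_like(b), np.zeros_like(b)) for b in self.intercepts_],
        )
        self.loss_curve_ = []
        self.validation_curve_ = [] if validation_data is not None else None

        t = 0
        n = len(x)
        for _ in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            for start in range(0, n, self.batch_size):
                t += 1
                batch = order[start : start + self.batch_size]
                self._batch_step(x[batch], yv[batch], adam_state, t)
            train_mse = float(np.mean((self._forward(x)[:, 0] - yv) ** 2))
            if not np.isfinite(train_mse):
                raise TrainingDivergedError(f"training MSE became {train_mse}")
            self.loss_curve_.append(train_mse)
            if validation_data is not None:
                xv = np.asarray(validation_data[0], dtype=float)
                yvv = np.asarray(validation_data[1], dtype=float).ravel()
                self.validation_curve_.append(
                    float(np.mean((self._forward(xv)[:, 0] - yvv) ** 2))
                )

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_features_in_:
            raise InvalidParameterError(
                f"X must be (n, {self.n_features_in_}), got {x.shape}"
            )
        return self._forward(x)[:, 0]
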