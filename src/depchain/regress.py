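"""Voltage regression harness: preprocessing, metrics, rank costs, a small
from-scratch multilayer perceptron and two baseline regressors.

Evaluation metrics for an actual/predicted pair set (y, y_hat):

    MAE  = mean |y - y_hat|
    MRE  = mean |y - y_hat| / y           (requires y != 0)
    MSE  = mean (y - y_hat)^2
    R^2  = 1 - sum (y - y_hat)^2 / sum (y - y_mean)^2
    RMSE = sqrt(MSE)
    accuracy = fraction with |y - y_hat| < 0.5   (strict half-volt band)

Voltage prediction is framed as an ordinal problem: the K applied voltages
act as sorted ranks u_1 < ... < u_K with absolute cost C[y, u] = |y - u|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .optim import OptimizerState, optimizer_step


# --- preprocessing ----------------------------------------------------------

def impute_median(X: np.ndarray) -> np.ndarray:
    """Replace NaNs with the per-column median of the observed values
    (median of an even count = mean of the two middle values)."""
    X = np.array(X, dtype=float, copy=True)
    for j in range(X.shape[1]):
        col = X[:, j]
        missing = np.isnan(col)
        if missing.all():
            raise ValueError(f"column {j} is fully missing; cannot impute")
        if missing.any():
            col[missing] = np.median(col[~missing])
    return X


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    train_fraction: float = 0.8,
    seed: int = 42,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Uniform random split without replacement; returns ((Xtr, ytr), (Xte, yte))."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    X = np.asarray(X)
    y = np.asarray(y)
    n = len(y)
    n_train = int(round(n * train_fraction))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"degenerate split sizes for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    return (X[tr], y[tr]), (X[te], y[te])


# --- metrics ----------------------------------------------------------------

@dataclass(frozen=True)
class RegressionReport:
    """MAE, MRE, MSE, RMSE, R^2 and half-volt accuracy for one (y, y_hat) set.

    `mre` is None when any actual value is zero (relative error undefined).
    """

    mae: float
    mse: float
    rmse: float
    r_squared: float
    accuracy: float
    n: int
    mre: float | None = None

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mre": self.mre,
            "mse": self.mse,
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "accuracy": self.accuracy,
            "n": self.n,
        }


def evaluate(y: np.ndarray, y_hat: np.ndarray) -> RegressionReport:
    """Compute the full metric report for actual vs predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 1:
        raise ValueError("y and y_hat must be equal-length 1-D with n >= 1")
    err = y - y_hat
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    else:
        r2 = 1.0 if mse == 0 else float("-inf")
    accuracy = float(np.mean(np.abs(err) < 0.5))
    mre = None
    if np.all(y != 0):
        mre = float(np.mean(np.abs(err) / y))
    return RegressionReport(
        mae=mae, mse=mse, rmse=rmse, r_squared=r2,
        accuracy=accuracy, n=len(y), mre=mre,
    )


def rank_cost_matrix(ranks: np.ndarray) -> np.ndarray:
    """Absolute cost matrix C[i, j] = |u_i - u_j| over sorted distinct ranks."""
    u = np.asarray(ranks, dtype=float)
    if u.ndim != 1 or len(u) < 1:
        raise ValueError("ranks must be a non-empty 1-D array")
    if len(np.unique(u)) != len(u):
        raise ValueError("ranks must be distinct")
    if not np.all(np.diff(u) > 0):
        raise ValueError("ranks must be sorted ascending")
    return np.abs(u[:, None] - u[None, :])


# --- models -----------------------------------------------------------------

class MLPRegressor:
    """Single-hidden-layer network (ReLU hidden, linear output) trained by
    mini-batch gradient descent on the mean-squared (Euclidean) loss.

    The output bias is initialized to the training-target mean so the network
    starts from the null model and only has to learn deviations; hidden
    weights use He initialization.  The optimizer is one of sgdm / rmsprop /
    adam with the update rules of :mod:`depchain.optim`.
    """

    def __init__(
        self,
        hidden: int = 32,
        optimizer: str = "adam",
        alpha: float = 1e-4,
        batch_size: int = 10,
        epochs: int = 100,
        seed: int = 42,
        beta: float = 0.9,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
    ) -> None:
        self.hidden = hidden
        self.optimizer = optimizer
        self.alpha = alpha
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.beta, self.beta1, self.beta2, self.epsilon = beta, beta1, beta2, epsilon
        self.loss_history: list[float] = []

    def _init_params(self, n_features: int, y_mean: float) -> None:
        rng = np.random.default_rng(self.seed)
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / n_features), (n_features, self.hidden))
        self.b1 = np.zeros(self.hidden)
        self.w2 = rng.normal(0.0, np.sqrt(1.0 / self.hidden), (self.hidden, 1))
        self.b2 = np.full(1, y_mean)
        self._states = {
            name: OptimizerState(
                kind=self.optimizer, alpha=self.alpha, beta=self.beta,
                beta1=self.beta1, beta2=self.beta2, epsilon=self.epsilon,
            )
            for name in ("w1", "b1", "w2", "b2")
        }

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.maximum(X @ self.w1 + self.b1, 0.0)
        return h, (h @ self.w2 + self.b2).ravel()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) == 0:
            raise ValueError("empty training set")
        self._init_params(X.shape[1], float(y.mean()))
        rng = np.random.default_rng(self.seed + 1)
        n = len(X)
        self.loss_history = []
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                h, pred = self._forward(xb)
                err = pred - yb
                epoch_losses.append(float(np.mean(err**2)))
                m = len(idx)
                d_out = (2.0 / m) * err[:, None]  # dL/d(pre-output), (m, 1)
                g_w2 = h.T @ d_out
                g_b2 = d_out.sum(axis=0)
                d_h = (d_out @ self.w2.T) * (h > 0)
                g_w1 = xb.T @ d_h
                g_b1 = d_h.sum(axis=0)
                self.w1 = optimizer_step(self._states["w1"], self.w1, g_w1)
                self.b1 = optimizer_step(self._states["b1"], self.b1, g_b1)
                self.w2 = optimizer_step(self._states["w2"], self.w2, g_w2)
                self.b2 = optimizer_step(self._states["b2"], self.b2, g_b2)
            loss = float(np.mean(epoch_losses))
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch + 1}")
            self.loss_history.append(loss)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[1]


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int = 32,
    optimizer: str = "adam",
    alpha: float = 1e-4,
    batch_size: int = 10,
    epochs: int = 100,
    seed: int = 42,
) -> MLPRegressor:
    """Fit the from-scratch MLP on (X, y) and return the trained model.

    With epochs=0 the model keeps its (seeded) initialization, whose output
    is the training-target mean plus the random hidden contribution.
    """
    model = MLPRegressor(
        hidden=hidden, optimizer=optimizer, alpha=alpha,
        batch_size=batch_size, epochs=epochs, seed=seed,
    )
    if epochs == 0:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        model._init_params(X.shape[1], float(y.mean()))
        model.loss_history = []
        return model
    return model.fit(X, y)


class KNNRegressor:
    """k-nearest-neighbor regression: mean target of the k Euclidean-nearest
    training points (distance ties broken by training index)."""

    def __init__(self, k: int = 5) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNRegressor":
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.X) == 0:
            raise ValueError("empty training set")
        if self.k > len(self.X):
            raise ValueError(f"k={self.k} exceeds n_train={len(self.X)}")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = cdist(np.asarray(X, dtype=float), self.X)
        order = np.lexsort(
            (np.broadcast_to(np.arange(d.shape[1]), d.shape), d), axis=1
        )
        return self.y[order[:, : self.k]].mean(axis=1)


class LinearRegressionOLS:
    """Ordinary least squares with intercept, solved via numpy lstsq."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearRegressionOLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) == 0:
            raise ValueError("empty training set")
        A = np.column_stack([np.ones(len(X)), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def baseline_regressors(
    X: np.ndarray, y: np.ndarray, k: int = 5
) -> dict[str, object]:
    """Fit the in-package baselines (kNN and OLS) on the training set."""
    return {
        "knn": KNNRegressor(k=k).fit(X, y),
        "linear": LinearRegressionOLS().fit(X, y),
    }
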