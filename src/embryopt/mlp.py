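"""Three-layer perceptron trained with Levenberg-Marquardt, the comparison
model for the SVR surrogate.

Architecture: input -> one hidden layer with hyperbolic-tangent activation
-> linear output.  Training minimizes the sum of squared errors on scaled
data with damped Gauss-Newton steps ``dw = -(J'J + mu I)^-1 J'e``, where J
is the analytic Jacobian of the residuals; the damping mu shrinks on
accepted steps and grows on rejected ones, interpolating between
Gauss-Newton and a vanishing gradient-descent step.  A held-out slice of
the training rows provides early stopping; the weights with the best
validation error are returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FACTOR_NAMES, RESPONSE_BOUNDS
from .preprocess import ScalingParams

__all__ = ["MLPModel", "LMConfig", "mlp_forward", "fit_mlp", "tune_mlp"]


@dataclass
class MLPModel:
    """Weights of a 3-layer perceptron (tanh hidden, identity output)."""

    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    scaler: ScalingParams | None = None
    target_name: str | None = None
    input_names: tuple[str, ...] = FACTOR_NAMES

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    def forward_scaled(self, X_scaled: np.ndarray) -> np.ndarray:
        X_scaled = np.atleast_2d(np.asarray(X_scaled, float))
        if X_scaled.shape[1] != self.W1.shape[1]:
            raise ValueError(
                f"expected {self.W1.shape[1]} input dims, got {X_scaled.shape[1]}"
            )
        h = np.tanh(X_scaled @ self.W1.T + self.b1)
        return h @ self.W2 + self.b2

    def predict(self, X: np.ndarray | pd.DataFrame, clip: bool = False) -> np.ndarray:
        """Predict in natural units from natural-unit inputs (needs scaler)."""
        if self.scaler is None or self.target_name is None:
            raise ValueError("model has no scaler attached; use forward_scaled")
        if isinstance(X, pd.DataFrame):
            X = X[list(self.input_names)].to_numpy(float)
        Xs = self.scaler.apply_array(np.atleast_2d(X), list(self.input_names))
        y = self.scaler.invert_array(self.forward_scaled(Xs), [self.target_name])
        if clip:
            lo, hi = RESPONSE_BOUNDS[self.target_name]
            y = np.clip(y, lo, hi)
        return y

    # --- flat parameter vector helpers -------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2, [self.b2]])

    def set_params(self, w: np.ndarray) -> None:
        h, d = self.W1.shape
        self.W1 = w[: h * d].reshape(h, d)
        self.b1 = w[h * d : h * d + h]
        self.W2 = w[h * d + h : h * d + 2 * h]
        self.b2 = float(w[-1])

    def to_json(self) -> str:
        return json.dumps(
            {
                "hidden_size": self.hidden_size,
                "input_names": list(self.input_names),
                "target_name": self.target_name,
                "W1": self.W1.tolist(),
                "b1": self.b1.tolist(),
                "W2": self.W2.tolist(),
                "b2": self.b2,
                "scaler": None
                if self.scaler is None
                else json.loads(self.scaler.to_json()),
            }
        )


def mlp_forward(model: MLPModel, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Predictions in natural units (functional alias of ``predict``)."""
    return model.predict(X)


@dataclass
class LMConfig:
    """Levenberg-Marquardt training configuration."""

    max_epochs: int = 1000
    mu0: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10
    grad_tol: float = 1e-7
    val_fraction: float = 0.15
    patience: int = 25
    seed: int = 0
    hidden_sizes: tuple[int, ...] = (3, 5, 8, 12, 15)

    def __post_init__(self) -> None:
        if not self.mu_increase > 1.0:
            raise ValueError("mu_increase must be > 1")
        if not 0.0 < self.mu_decrease < 1.0:
            raise ValueError("mu_decrease must be in (0, 1)")
        if self.grad_tol <= 0:
            raise ValueError("grad_tol must be > 0")
        if len(self.hidden_sizes) == 0:
            raise ValueError("hidden size candidate list is empty")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")


def _init_model(
    hidden: int, n_in: int, rng: np.random.Generator
) -> MLPModel:
    # uniform in [-0.5, 0.5] scaled by fan-in, for reproducible small starts
    W1 = rng.uniform(-0.5, 0.5, size=(hidden, n_in)) / np.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, size=hidden) / np.sqrt(n_in)
    W2 = rng.uniform(-0.5, 0.5, size=hidden) / np.sqrt(hidden)
    b2 = float(rng.uniform(-0.5, 0.5))
    return MLPModel(W1=W1, b1=b1, W2=W2, b2=b2)


def _jacobian(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d yhat_i / d w_p of the network output, (n, P)."""
    n = len(X)
    h = np.tanh(X @ model.W1.T + model.b1)  # (n, H)
    dtanh = 1.0 - h**2
    # output wrt W1[k, j]: W2[k] * (1 - h_k^2) * x_j
    g = model.W2 * dtanh  # (n, H)
    J_W1 = g[:, :, None] * X[:, None, :]  # (n, H, n_in)
    J_b1 = g
    J_W2 = h
    J_b2 = np.ones((n, 1))
    return np.concatenate([J_W1.reshape(n, -1), J_b1, J_W2, J_b2], axis=1)


def _lm_train(
    model: MLPModel,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    config: LMConfig,
) -> tuple[MLPModel, dict]:
    """Damped Gauss-Newton loop with early stopping; returns best-val model."""
    w = model.get_params()
    mu = config.mu0
    model.set_params(w)
    resid = model.forward_scaled(Xtr) - ytr
    sse = float(resid @ resid)
    best_val = np.inf
    best_w = w.copy()
    stall = 0
    history = {"train_sse": [], "val_sse": [], "epochs": 0}

    for epoch in range(config.max_epochs):
        J = _jacobian(model, Xtr)
        grad = J.T @ resid
        if np.max(np.abs(grad)) < config.grad_tol:
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            A = JtJ + mu * np.eye(len(w))
            try:
                step = np.linalg.solve(A, -grad)
            except np.linalg.LinAlgError:
                mu *= config.mu_increase
                continue
            w_new = w + step
            model.set_params(w_new)
            resid_new = model.forward_scaled(Xtr) - ytr
            sse_new = float(resid_new @ resid_new)
            if not np.isfinite(sse_new):
                raise FloatingPointError("non-finite training loss")
            if sse_new <= sse:
                w, resid, sse = w_new, resid_new, sse_new
                mu = max(mu * config.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            break  # damping exhausted; cannot decrease SSE further
        model.set_params(w)
        if len(Xval):
            val_res = model.forward_scaled(Xval) - yval
            val_sse = float(val_res @ val_res)
        else:
            val_sse = sse
        history["train_sse"].append(sse)
        history["val_sse"].append(val_sse)
        if val_sse < best_val - 1e-15:
            best_val = val_sse
            best_w = w.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    history["epochs"] = len(history["train_sse"])
    model.set_params(best_w)
    return model, history


def fit_mlp(
    train: pd.DataFrame,
    target_name: str,
    scaler: ScalingParams,
    config: LMConfig | None = None,
    hidden_size: int | None = None,
    input_names: tuple[str, ...] = FACTOR_NAMES,
) -> MLPModel:
    """Train one MLP response model on a replicate table.

    A ``val_fraction`` slice of the rows (random, seeded) is held out for
    early stopping; the returned model carries the scaler so ``predict``
    works in natural units.  Deterministic per ``config.seed``.
    """
    if config is None:
        config = LMConfig()
    if hidden_size is None:
        hidden_size = config.hidden_sizes[0]
    if len(train) < 10:
        raise ValueError("need at least 10 training rows")

    Xs = scaler.apply_array(train[list(input_names)].to_numpy(float), list(input_names))
    ys = scaler.apply_array(train[[target_name]].to_numpy(float), [target_name]).ravel()

    rng = np.random.default_rng(config.seed)
    n = len(Xs)
    n_val = int(round(config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    model = _init_model(hidden_size, Xs.shape[1], rng)
    model, _ = _lm_train(model, Xs[tr_idx], ys[tr_idx], Xs[val_idx], ys[val_idx], config)
    model.scaler = scaler
    model.target_name = target_name
    model.input_names = tuple(input_names)
    return model


def tune_mlp(
    train: pd.DataFrame,
    target_name: str,
    scaler: ScalingParams,
    config: LMConfig | None = None,
    input_names: tuple[str, ...] = FACTOR_NAMES,
) -> MLPModel:
    """Pick the hidden size with the lowest validation RMSE, then refit.

    Candidates share the same seed (hence the same validation slice and
    comparable scores); the winner is retrained on the full training
    partition with a fresh internal early-stopping split.
    """
    if config is None:
        config = LMConfig()
    if not config.hidden_sizes:
        raise ValueError("hidden size candidate list is empty")

    Xs = scaler.apply_array(train[list(input_names)].to_numpy(float), list(input_names))
    ys = scaler.apply_array(train[[target_name]].to_numpy(float), [target_name]).ravel()
    n = len(Xs)
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    best: tuple[float, int] | None = None
    for h in config.hidden_sizes:
        model = _init_model(h, Xs.shape[1], np.random.default_rng(config.seed + h))
        model, hist = _lm_train(
            model, Xs[tr_idx], ys[tr_idx], Xs[val_idx], ys[val_idx], config
        )
        val_rmse = float(
            np.sqrt(np.mean((model.forward_scaled(Xs[val_idx]) - ys[val_idx]) ** 2))
        )
        if best is None or val_rmse < best[0]:
            best = (val_rmse, h)
    return fit_mlp(
        train, target_name, scaler, config=config, hidden_size=best[1],
        input_names=input_names,
    )
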