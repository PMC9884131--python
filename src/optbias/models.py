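"""Regularized estimators built around the one-sided penalty.

Two model families are provided:

* :func:`fit_linear` — linear regression ``h(x) = W·x + b`` minimizing
  mean squared error + (beta/2)·Psi + classical l1/l2 terms.  The
  objective is convex (strictly convex for p > 1 with the squared base
  loss), so the quasi-Newton solution is the global minimum.
* :func:`fit_svr` — epsilon-insensitive support-vector regression solved
  in the primal: (1/2)||w||^2 + C·sum max(0, |e_i| - eps) + (beta/2)·Psi,
  with linear or RBF kernel.

:func:`make_loss_plugin` exposes the penalized squared-error loss and its
prediction-space gradient as plain callables, so externally trained
gradient-based models (e.g. recurrent networks) can adopt the same
penalty without depending on this package's solvers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.optimize import minimize

from .penalty import PenaltyConfig, psi, psi_gradient

__all__ = [
    "FitConfig",
    "SVRConfig",
    "FittedLinearModel",
    "FittedSVRModel",
    "fit_linear",
    "predict",
    "fit_svr",
    "make_loss_plugin",
    "linear_objective",
    "svr_objective",
]


@dataclass(frozen=True)
class FitConfig:
    """Configuration for :func:`fit_linear`.

    ``lambda_l2``/``lambda_l1`` weight the classical ridge/lasso terms on
    the coefficients (the intercept is never penalized).  ``tolerance`` is
    the gradient-norm convergence threshold.
    """

    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    lambda_l2: float = 0.0
    lambda_l1: float = 0.0
    tolerance: float = 1e-8
    max_iterations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_l2 < 0 or self.lambda_l1 < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class SVRConfig:
    """Configuration for :func:`fit_svr` (primal epsilon-insensitive SVR)."""

    C: float = 1.0
    epsilon: float = 0.1
    kernel: Literal["linear", "rbf"] = "linear"
    gamma: float | None = None  # default 1/d, resolved at fit time
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    tolerance: float = 1e-8
    max_iterations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class FittedLinearModel:
    """Linear model ``h(x) = W·x + b`` with fit diagnostics."""

    W: np.ndarray
    b: float
    converged: bool
    n_iterations: int
    final_cost: float
    final_gradient_norm: float = np.nan

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def to_dict(self) -> dict:
        return {
            "model": "linear",
            "W": np.asarray(self.W, dtype=float).tolist(),
            "b": float(self.b),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "final_cost": float(self.final_cost),
            "final_gradient_norm": float(self.final_gradient_norm),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedLinearModel":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            b=float(d["b"]),
            converged=bool(d["converged"]),
            n_iterations=int(d["n_iterations"]),
            final_cost=float(d["final_cost"]),
            final_gradient_norm=float(d.get("final_gradient_norm", np.nan)),
        )

    @classmethod
    def from_json(cls, path) -> "FittedLinearModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FittedSVRModel:
    """Primal SVR model: linear (``w``, ``b``) or kernelized
    (dual-style coefficients ``alpha`` over the training points)."""

    kernel: str
    b: float
    converged: bool
    n_iterations: int
    final_cost: float
    w: np.ndarray | None = None          # linear kernel
    alpha: np.ndarray | None = None      # rbf kernel
    X_train: np.ndarray | None = None    # rbf kernel support points
    gamma: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _check_matrix(X)
        if self.kernel == "linear":
            return X @ self.w + self.b
        K = _rbf_kernel(X, self.X_train, self.gamma)
        return K @ self.alpha + self.b

    def to_dict(self) -> dict:
        d = {
            "model": "svr",
            "kernel": self.kernel,
            "b": float(self.b),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "final_cost": float(self.final_cost),
        }
        if self.kernel == "linear":
            d["w"] = np.asarray(self.w, dtype=float).tolist()
        else:
            d["alpha"] = np.asarray(self.alpha, dtype=float).tolist()
            d["X_train"] = np.asarray(self.X_train, dtype=float).tolist()
            d["gamma"] = float(self.gamma)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedSVRModel":
        kw = dict(
            kernel=d["kernel"],
            b=float(d["b"]),
            converged=bool(d["converged"]),
            n_iterations=int(d["n_iterations"]),
            final_cost=float(d["final_cost"]),
        )
        if d["kernel"] == "linear":
            kw["w"] = np.asarray(d["w"], dtype=float)
        else:
            kw["alpha"] = np.asarray(d["alpha"], dtype=float)
            kw["X_train"] = np.asarray(d["X_train"], dtype=float)
            kw["gamma"] = float(d["gamma"])
        return cls(**kw)

    @classmethod
    def from_json(cls, path) -> "FittedSVRModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-d matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = _check_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError(f"dimension mismatch: X has {X.shape[0]} rows, y has {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return X, y


def linear_objective(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, config: FitConfig
) -> float:
    """Value of the penalized linear-regression objective at ``params``
    (= [W, b]); useful for convexity probes and independent oracles."""
    W, b = params[:-1], params[-1]
    e = X @ W + b - y
    base = float(np.mean(e**2))
    value = base + 0.5 * config.penalty.beta * psi(e, config.penalty)
    value += config.lambda_l2 * float(W @ W) + config.lambda_l1 * float(np.sum(np.abs(W)))
    return value


def _linear_value_grad(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, config: FitConfig
) -> tuple[float, np.ndarray]:
    n = X.shape[0]
    W, b = params[:-1], params[-1]
    e = X @ W + b - y
    value = float(np.mean(e**2)) + 0.5 * config.penalty.beta * psi(e, config.penalty)
    value += config.lambda_l2 * float(W @ W) + config.lambda_l1 * float(np.sum(np.abs(W)))
    # d/de of mean(e^2) + (beta/2) Psi
    g_e = 2.0 * e / n + 0.5 * config.penalty.beta * psi_gradient(e, config.penalty)
    gW = X.T @ g_e + 2.0 * config.lambda_l2 * W + config.lambda_l1 * np.sign(W)
    gb = float(np.sum(g_e))
    return value, np.concatenate([gW, [gb]])


def fit_linear(X: np.ndarray, y: np.ndarray, config: FitConfig | None = None) -> FittedLinearModel:
    """Fit the penalized linear regression by quasi-Newton minimization.

    The objective is ``mean((h(X)-y)^2) + (beta/2) Psi + lambda_l2 ||W||^2
    + lambda_l1 ||W||_1``; initialization is W = 0, b = mean(y).  For the
    convex objective the returned stationary point is the global minimum;
    ``converged`` is False if the gradient norm is still above tolerance
    after ``max_iterations``.
    """
    config = config or FitConfig()
    X, y = _check_xy(X, y)
    x0 = np.concatenate([np.zeros(X.shape[1]), [float(np.mean(y))]])
    res = minimize(
        _linear_value_grad,
        x0,
        args=(X, y, config),
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iterations,
            "gtol": config.tolerance,
            "ftol": 1e-15,
            "maxls": 60,
        },
    )
    gnorm = float(np.linalg.norm(_linear_value_grad(res.x, X, y, config)[1]))
    return FittedLinearModel(
        W=res.x[:-1].copy(),
        b=float(res.x[-1]),
        converged=bool(gnorm <= max(config.tolerance, 1e-6)),
        n_iterations=int(res.nit),
        final_cost=float(res.fun),
        final_gradient_norm=gnorm,
    )


def predict(model: FittedLinearModel, X: np.ndarray) -> np.ndarray:
    """Row-wise ``X·W + b``."""
    X = _check_matrix(X)
    W = np.asarray(model.W, dtype=float)
    if X.shape[1] != W.size:
        raise ValueError(f"dimension mismatch: model expects d={W.size}, got {X.shape[1]}")
    return X @ W + model.b


# ---------------------------------------------------------------------------
# SVR in the primal

#: softplus smoothing width for the epsilon-insensitive hinge; the
#: smoothing error in the objective is below 2*C*n*mu*ln(2)
_HINGE_MU = 1e-6


def _smooth_hinge(t: np.ndarray, mu: float = _HINGE_MU) -> tuple[np.ndarray, np.ndarray]:
    """Softplus approximation of max(0, t) and its derivative."""
    val = mu * np.logaddexp(0.0, t / mu)
    der = 1.0 / (1.0 + np.exp(np.clip(-t / mu, -700, 700)))
    return val, der


def _eps_insensitive(e: np.ndarray, eps: float) -> np.ndarray:
    return np.maximum(0.0, np.abs(e) - eps)


def _rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    sq = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


def svr_objective(model: FittedSVRModel, X: np.ndarray, y: np.ndarray, config: SVRConfig) -> float:
    """Exact (unsmoothed) primal SVR objective of a fitted model:
    (1/2)||w||^2 + C sum max(0,|e|-eps) + (beta/2) Psi(e)."""
    X, y = _check_xy(X, y)
    pred = model.predict(X)
    e = pred - y
    if model.kernel == "linear":
        norm2 = float(model.w @ model.w)
    else:
        K = _rbf_kernel(model.X_train, model.X_train, model.gamma)
        norm2 = float(model.alpha @ K @ model.alpha)
    value = 0.5 * norm2 + config.C * float(np.sum(_eps_insensitive(e, config.epsilon)))
    value += 0.5 * config.penalty.beta * psi(e, config.penalty)
    return value


def fit_svr(X: np.ndarray, y: np.ndarray, config: SVRConfig | None = None) -> FittedSVRModel:
    """Fit epsilon-insensitive SVR in the primal with the one-sided penalty.

    The constrained slack formulation is equivalent to the unconstrained
    hinge form minimized here; the hinge is softplus-smoothed (width 1e-6)
    so quasi-Newton iteration applies.  Residuals strictly inside the
    epsilon tube contribute nothing.  Deterministic for fixed inputs.
    """
    config = config or SVRConfig()
    X, y = _check_xy(X, y)
    n, d = X.shape
    eps, C = config.epsilon, config.C
    pen = config.penalty

    if config.kernel == "linear":
        K = None
        n_coef = d
    else:
        gamma = config.gamma if config.gamma is not None else 1.0 / d
        K = _rbf_kernel(X, X, gamma)
        n_coef = n

    def value_grad(params: np.ndarray) -> tuple[float, np.ndarray]:
        coef, b = params[:-1], params[-1]
        if K is None:
            pred = X @ coef + b
            norm2 = coef @ coef
            norm_grad = 2.0 * coef
        else:
            Kc = K @ coef
            pred = Kc + b
            norm2 = coef @ Kc
            norm_grad = 2.0 * Kc
        e = pred - y
        h_up, d_up = _smooth_hinge(e - eps)
        h_lo, d_lo = _smooth_hinge(-e - eps)
        value = 0.5 * norm2 + C * float(np.sum(h_up + h_lo))
        value += 0.5 * pen.beta * psi(e, pen)
        g_e = C * (d_up - d_lo) + 0.5 * pen.beta * psi_gradient(e, pen)
        if K is None:
            g_coef = X.T @ g_e + 0.5 * norm_grad
        else:
            g_coef = K.T @ g_e + 0.5 * norm_grad
        return value, np.concatenate([g_coef, [float(np.sum(g_e))]])

    x0 = np.concatenate([np.zeros(n_coef), [float(np.median(y))]])
    res = minimize(
        value_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iterations,
            "gtol": config.tolerance,
            "ftol": 1e-15,
            "maxls": 60,
        },
    )
    coef, b = res.x[:-1], float(res.x[-1])
    gnorm = float(np.linalg.norm(value_grad(res.x)[1]))
    if config.kernel == "linear":
        return FittedSVRModel(
            kernel="linear", w=coef.copy(), b=b,
            converged=bool(res.success or gnorm <= 1e-4),
            n_iterations=int(res.nit), final_cost=float(res.fun),
        )
    return FittedSVRModel(
        kernel="rbf", alpha=coef.copy(), X_train=X.copy(),
        gamma=config.gamma if config.gamma is not None else 1.0 / d, b=b,
        converged=bool(res.success or gnorm <= 1e-4),
        n_iterations=int(res.nit), final_cost=float(res.fun),
    )


def make_loss_plugin(
    config: PenaltyConfig,
) -> tuple[
    Callable[[np.ndarray, np.ndarray], float],
    Callable[[np.ndarray, np.ndarray], np.ndarray],
]:
    """Penalized squared-error loss as a (value, gradient) callable pair.

    ``value(predictions, targets)`` returns
    ``mean((pred-y)^2) + (beta/2) Psi(pred - y)`` and
    ``gradient(predictions, targets)`` its derivative with respect to the
    predictions — the contract any externally trained gradient-based
    model (e.g. a recurrent network) needs to adopt the penalty.
    """

    def value(predictions: np.ndarray, targets: np.ndarray) -> float:
        e = np.asarray(predictions, float) - np.asarray(targets, float)
        return float(np.mean(e**2)) + 0.5 * config.beta * psi(e, config)

    def gradient(predictions: np.ndarray, targets: np.ndarray) -> np.ndarray:
        e = np.asarray(predictions, float) - np.asarray(targets, float)
        return 2.0 * e / e.size + 0.5 * config.beta * psi_gradient(e, config)

    return value, gradient
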