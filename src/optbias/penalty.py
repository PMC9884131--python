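"""One-sided (optimism-bias) penalty for regression losses.

The penalty targets a *specific side* of the residual distribution.  With
signed residuals ``e_i = h(X_i) - y_i`` (positive = over-prediction), the
penalty is

    Psi(e) = sum_i (sgn(e_i) + 1) * |e_i|**p        (direction="over")
    Psi(e) = sum_i (-sgn(e_i) + 1) * |e_i|**p       (direction="under")

i.e. residuals on the penalized side count twice their |e|^p, residuals on
the other side count nothing.  Added to any convex base loss as
``base + (beta/2) * Psi`` the objective stays convex for ``beta >= 0`` and
``p >= 1``, and strictly convex whenever the base loss is.

Sign convention used throughout the package: positive residual means the
prediction lies *above* the actual value (over-prediction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

Direction = Literal["over", "under"]

__all__ = [
    "PenaltyConfig",
    "signed_residuals",
    "psi",
    "psi_gradient",
    "total_cost",
    "check_midpoint_convexity",
]

#: absolute slack allowed in midpoint-convexity checks (floating-point noise
#: on well-scaled costs)
CONVEXITY_TOL = 1e-9


@dataclass(frozen=True)
class PenaltyConfig:
    """Parameters of the one-sided penalty.

    Parameters
    ----------
    direction
        Which side of the residual distribution to penalize: ``"over"``
        penalizes over-predictions (e > 0), ``"under"`` penalizes
        under-predictions (e < 0).
    p
        Exponent of the |e|^p term; must be >= 1 (p = 2 is the standard
        choice and the package default).
    beta
        Penalty weight; must be >= 0.  ``beta = 0`` disables the penalty.
    normalization
        ``"mean"`` divides Psi by the number of residuals so that beta is
        comparable across sample sizes (default); ``"sum"`` keeps the raw
        sum.
    """

    direction: Direction = "over"
    p: float = 2.0
    beta: float = 0.0
    normalization: Literal["sum", "mean"] = "mean"

    def __post_init__(self) -> None:
        if self.direction not in ("over", "under"):
            raise ValueError(f"direction must be 'over' or 'under', got {self.direction!r}")
        if not np.isfinite(self.p) or self.p < 1:
            raise ValueError(f"p must be a finite real >= 1, got {self.p}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"beta must be a finite real >= 0, got {self.beta}")
        if self.normalization not in ("sum", "mean"):
            raise ValueError(f"normalization must be 'sum' or 'mean', got {self.normalization!r}")

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "p": self.p,
            "beta": self.beta,
            "normalization": self.normalization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenaltyConfig":
        return cls(**d)


def _as_residuals(values: np.ndarray) -> np.ndarray:
    e = np.asarray(values, dtype=float)
    if e.ndim != 1 or e.size < 1:
        raise ValueError("residuals must be a non-empty 1-d vector")
    if not np.all(np.isfinite(e)):
        raise ValueError("residuals contain non-finite values")
    return e


def signed_residuals(predictions: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Element-wise signed residuals ``prediction - target``.

    Positive entries are over-predictions, negative entries
    under-predictions.  Order is preserved.
    """
    pred = np.asarray(predictions, dtype=float)
    act = np.asarray(targets, dtype=float)
    if pred.shape != act.shape:
        raise ValueError(f"length mismatch: predictions {pred.shape} vs targets {act.shape}")
    if pred.ndim != 1 or pred.size < 1:
        raise ValueError("inputs must be non-empty 1-d vectors")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(act))):
        raise ValueError("non-finite input")
    return pred - act


def _side_weights(e: np.ndarray, direction: Direction) -> np.ndarray:
    # (sgn(e)+1) for "over", (-sgn(e)+1) for "under"; sgn(0) := 0 so an
    # exact hit contributes weight 1 but |0|^p = 0 anyway.
    s = np.sign(e)
    return s + 1.0 if direction == "over" else -s + 1.0


def psi(residuals: np.ndarray, config: PenaltyConfig) -> float:
    """One-sided penalty value; >= 0, and 0 iff no residual lies strictly
    on the penalized side."""
    e = _as_residuals(residuals)
    value = float(np.sum(_side_weights(e, config.direction) * np.abs(e) ** config.p))
    if config.normalization == "mean":
        value /= e.size
    return value


def psi_gradient(residuals: np.ndarray, config: PenaltyConfig) -> np.ndarray:
    """Element-wise derivative of the Psi summand with respect to residuals.

    On the penalized side the summand is ``2|e|^p`` with derivative
    ``2 p |e|^(p-1) sgn(e)``; on the other side it is 0.  At ``e = 0`` the
    subgradient element 0 is returned (for p = 1 this is a subgradient, for
    p > 1 the true derivative).
    """
    e = _as_residuals(residuals)
    p = config.p
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.where(e != 0.0, np.abs(e) ** (p - 1.0), 0.0)
    grad = _side_weights(e, config.direction) * p * mag * np.sign(e)
    if config.normalization == "mean":
        grad = grad / e.size
    return grad


def total_cost(base_loss: float, residuals: np.ndarray, config: PenaltyConfig) -> float:
    """Regularized objective ``base_loss + (beta/2) * Psi(residuals)``."""
    if not np.isfinite(base_loss):
        raise ValueError("base_loss must be finite")
    return float(base_loss) + 0.5 * config.beta * psi(residuals, config)


def check_midpoint_convexity(
    cost_at: Callable[[np.ndarray], float],
    a: np.ndarray,
    b: np.ndarray,
    tol: float = CONVEXITY_TOL,
) -> bool:
    """Midpoint convexity test: f((a+b)/2) <= (f(a)+f(b))/2 + tol.

    A numerical probe for convexity of a cost surface along the segment
    [a, b]; raises on non-finite evaluations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fa, fb, fm = cost_at(a), cost_at(b), cost_at(0.5 * (a + b))
    if not (np.isfinite(fa) and np.isfinite(fb) and np.isfinite(fm)):
        raise ValueError("non-finite cost evaluation in convexity check")
    return fm <= 0.5 * (fa + fb) + tol
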