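"""Asymmetric-error metrics and the replicate bias-variance protocol.

Residual convention: ``e = y_pred - y_true``; ``e > 0`` is an
over-prediction.  "Mean squared positive error" (MSPE) averages squared
residuals over the over-predicted instances only, "mean squared negative
error" (MSNE) over the under-predicted ones.  These satisfy exactly

    n * mse = n_over * mspe + n_under * msne

since exact hits contribute zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .penalty import signed_residuals

__all__ = [
    "EvaluationReport",
    "BiasVarianceResult",
    "evaluate",
    "count_underpredicted_days",
    "bias_variance_estimate",
]


@dataclass
class EvaluationReport:
    """Per-dataset error summary with side-specific components.

    ``r2_defined`` flags whether the coefficient of determination exists
    (it does not when the targets have zero variance; ``r2`` is then NaN,
    never an exception).
    """

    mse: float
    mspe: float
    msne: float
    r2: float
    n_over: int
    n_under: int
    n_exact: int
    over_rate: float
    under_rate: float
    r2_defined: bool = True

    @property
    def n(self) -> int:
        return self.n_over + self.n_under + self.n_exact

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mspe": self.mspe,
            "msne": self.msne,
            "r2": self.r2,
            "n_over": self.n_over,
            "n_under": self.n_under,
            "n_exact": self.n_exact,
            "over_rate": self.over_rate,
            "under_rate": self.under_rate,
            "r2_defined": self.r2_defined,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv_row(self) -> str:
        """Single CSV fragment (no header) consumed by the sweep driver."""
        cols = [
            self.mse, self.mspe, self.msne, self.r2,
            self.n_over, self.n_under, self.n_exact,
            self.over_rate, self.under_rate,
        ]
        return ",".join(f"{c:.10g}" for c in cols)


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """Compute MSE, side-specific squared errors, side rates and r²."""
    e = signed_residuals(y_pred, y_true)
    y = np.asarray(y_true, dtype=float)
    n = e.size
    over = e > 0
    under = e < 0
    n_over = int(np.sum(over))
    n_under = int(np.sum(under))
    mse = float(np.mean(e**2))
    mspe = float(np.mean(e[over] ** 2)) if n_over else 0.0
    msne = float(np.mean(e[under] ** 2)) if n_under else 0.0
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot > 0:
        r2, r2_defined = 1.0 - float(np.sum(e**2)) / ss_tot, True
    else:
        r2, r2_defined = float("nan"), False
    return EvaluationReport(
        mse=mse, mspe=mspe, msne=msne, r2=r2,
        n_over=n_over, n_under=n_under, n_exact=n - n_over - n_under,
        over_rate=n_over / n, under_rate=n_under / n,
        r2_defined=r2_defined,
    )


def count_underpredicted_days(y_true: np.ndarray, y_pred: np.ndarray) -> int:
    """Number of time points where the prediction falls strictly below
    the actual count."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    return int(np.sum(p < y))


class ReplicateGenerator(Protocol):
    """A seeded data source that also knows its noiseless truth."""

    def sample(self, seed: int):  # -> object with .X and .y
        ...

    def true_response(self, X: np.ndarray) -> np.ndarray:
        ...


@dataclass
class BiasVarianceResult:
    """Bias²/variance estimated from repeated fits on replicate datasets.

    At each test-grid point the variance of predictions across replicates
    and the squared gap between the mean prediction and the noiseless
    truth are computed, then averaged over the grid.  Per-replicate
    predictions and r² values are retained so other summaries (e.g.
    un-squared bias) can be derived.
    """

    bias_squared: float
    variance: float
    mean_r2: float
    n_replicates: int
    per_replicate_r2: np.ndarray = field(repr=False, default=None)
    predictions: np.ndarray = field(repr=False, default=None)  # (reps, grid)


def bias_variance_estimate(
    data_generator: ReplicateGenerator,
    model_factory: Callable[[np.ndarray, np.ndarray], object],
    n_replicates: int,
    test_grid: np.ndarray,
    seed: int,
) -> BiasVarianceResult:
    """Monte-Carlo bias-variance decomposition over replicate datasets.

    ``model_factory(X, y)`` must return an object with a
    ``predict(X) -> vector`` method.  Replicate seeds are spawned
    deterministically from ``seed``; a fit failure aborts with the
    replicate index identified.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    grid = np.asarray(test_grid, dtype=float)
    if grid.ndim == 1:
        grid = grid[:, None]
    truth = np.asarray(data_generator.true_response(grid), dtype=float).ravel()
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)

    preds = np.empty((n_replicates, grid.shape[0]))
    r2s = np.empty(n_replicates)
    for r in range(n_replicates):
        ds = data_generator.sample(int(rep_seeds[r]))
        try:
            model = model_factory(ds.X, ds.y)
        except Exception as exc:  # identify the failing replicate
            raise RuntimeError(f"replicate {r} (seed {rep_seeds[r]}) failed to fit") from exc
        preds[r] = np.asarray(model.predict(grid), dtype=float).ravel()
        r2s[r] = evaluate(ds.y, model.predict(ds.X)).r2

    mean_pred = preds.mean(axis=0)
    bias_sq = float(np.mean((mean_pred - truth) ** 2))
    variance = float(np.mean(preds.var(axis=0)))
    return BiasVarianceResult(
        bias_squared=bias_sq,
        variance=variance,
        mean_r2=float(np.mean(r2s)),
        n_replicates=n_replicates,
        per_replicate_r2=r2s,
        predictions=preds,
    )
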