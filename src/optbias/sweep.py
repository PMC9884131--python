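"""Beta-sweep experiment harness.

Replicates the simulation protocol behind the penalty's bias-variance
story: for each penalty weight beta on a grid, fit the model on replicate
synthetic datasets, estimate bias²/variance on a fixed test grid, and
average the asymmetric error metrics on the training data.  Replicate
seeds are derived from the master seed only (not from beta), so the beta
axis is a paired comparison on identical datasets and the grid can be
extended without disturbing earlier replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import bias_variance_estimate, evaluate
from .models import FitConfig, SVRConfig, fit_linear, fit_svr
from .penalty import PenaltyConfig
from .synthetic import (
    DEFAULT_INTERCEPT,
    DEFAULT_NOISE_SD,
    UNIVARIATE_COEFFS,
    LinearGenerator,
)

__all__ = ["SweepConfig", "BetaSweepResult", "run_beta_sweep"]

#: order and names of the sweep table columns (schema v1)
SWEEP_COLUMNS = [
    "beta", "variance", "bias_squared", "mean_r2",
    "mean_mspe", "mean_msne", "mean_over_rate", "mean_under_rate",
    "sd_r2", "sd_mspe", "sd_msne",
]


@dataclass(frozen=True)
class SweepConfig:
    """Full specification of a beta sweep (echoed into outputs)."""

    beta_grid: tuple = (0.0, 0.01, 0.1, 1.0, 10.0)
    direction: str = "over"
    p: float = 2.0
    normalization: str = "mean"
    n_replicates: int = 100
    n: int = 1000
    coefficients: tuple = UNIVARIATE_COEFFS
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = DEFAULT_NOISE_SD
    model: str = "linear"          # "linear" | "svr"
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    grid_points: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(self.beta_grid)
        if not grid or any(b < 0 for b in grid) or list(grid) != sorted(grid):
            raise ValueError("beta_grid must be non-empty, non-negative, sorted ascending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.model not in ("linear", "svr"):
            raise ValueError(f"unknown model {self.model!r}")

    def to_dict(self) -> dict:
        return {
            "beta_grid": list(self.beta_grid),
            "direction": self.direction,
            "p": self.p,
            "normalization": self.normalization,
            "n_replicates": self.n_replicates,
            "n": self.n,
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "model": self.model,
            "svr_C": self.svr_C,
            "svr_epsilon": self.svr_epsilon,
            "grid_points": self.grid_points,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = dict(d)
        for key in ("beta_grid", "coefficients"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class BetaSweepResult:
    """One row per beta, plus the echoed config."""

    table: pd.DataFrame
    config: SweepConfig
    per_replicate: dict = field(repr=False, default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def _model_factory(config: SweepConfig, beta: float, reports: list):
    penalty = PenaltyConfig(direction=config.direction, p=config.p,
                            beta=beta, normalization=config.normalization)

    def factory(X, y):
        if config.model == "linear":
            model = fit_linear(X, y, FitConfig(penalty=penalty))
        else:
            model = fit_svr(X, y, SVRConfig(C=config.svr_C, epsilon=config.svr_epsilon,
                                            kernel="linear", penalty=penalty))
        reports.append(evaluate(y, model.predict(X)))
        return model

    return factory


def run_beta_sweep(config: SweepConfig) -> BetaSweepResult:
    """Run the replicate sweep over the beta grid; fully seeded."""
    gen = LinearGenerator(n=config.n, coefficients=tuple(config.coefficients),
                          intercept=config.intercept, noise_sd=config.noise_sd)
    grid = gen.test_grid(config.grid_points)
    rows = []
    per_replicate: dict[float, list] = {}
    for beta in config.beta_grid:
        reports: list = []
        try:
            bv = bias_variance_estimate(
                gen, _model_factory(config, beta, reports),
                n_replicates=config.n_replicates, test_grid=grid, seed=config.seed,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"sweep aborted at beta={beta}: {exc}") from exc
        mspe = np.array([r.mspe for r in reports])
        msne = np.array([r.msne for r in reports])
        r2 = np.array([r.r2 for r in reports])
        rows.append({
            "beta": beta,
            "variance": bv.variance,
            "bias_squared": bv.bias_squared,
            "mean_r2": bv.mean_r2,
            "mean_mspe": float(mspe.mean()),
            "mean_msne": float(msne.mean()),
            "mean_over_rate": float(np.mean([r.over_rate for r in reports])),
            "mean_under_rate": float(np.mean([r.under_rate for r in reports])),
            "sd_r2": float(r2.std(ddof=1)) if len(r2) > 1 else 0.0,
            "sd_mspe": float(mspe.std(ddof=1)) if len(mspe) > 1 else 0.0,
            "sd_msne": float(msne.std(ddof=1)) if len(msne) > 1 else 0.0,
        })
        per_replicate[beta] = reports
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    if not np.all(np.isfinite(table.to_numpy())):
        raise RuntimeError("sweep produced non-finite summaries")
    return BetaSweepResult(table=table, config=config, per_replicate=per_replicate)
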