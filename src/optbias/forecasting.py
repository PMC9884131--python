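"""Sliding-window autoregressive forecasting with the one-sided penalty.

A desk-scale surrogate for surge forecasting with asymmetric costs: a
linear model is fit on lag windows of the count series, with
``direction="under"`` in the penalty pushing forecasts up so fewer days
are under-predicted during surges.  The architecture is deliberately the
simplest thing with a tunable loss; anything gradient-trained (including
recurrent networks) can adopt the same penalty through
:func:`optbias.models.make_loss_plugin`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, count_underpredicted_days, evaluate
from .models import FitConfig, FittedLinearModel, fit_linear
from .synthetic import TimeSeries

__all__ = [
    "WindowedSeries",
    "ForecastReport",
    "make_windows",
    "fit_forecaster",
    "rolling_evaluate",
    "write_predictions_csv",
]


@dataclass
class WindowedSeries:
    """Lag-window design matrix: row i holds counts[i .. i+w-1], target
    counts[i+w+h-1].  Every feature strictly precedes its target."""

    X: np.ndarray
    y: np.ndarray
    window_size: int
    horizon: int = 1

    @property
    def n_windows(self) -> int:
        return self.y.size


def make_windows(series: TimeSeries, window_size: int, horizon: int = 1) -> WindowedSeries:
    """Slice a series into contiguous lag windows with next-step targets."""
    counts = np.asarray(series.counts, dtype=float)
    if window_size < 1 or horizon < 1:
        raise ValueError("window_size and horizon must be >= 1")
    n_windows = counts.size - window_size - horizon + 1
    if n_windows < 1:
        raise ValueError(
            f"series of length {counts.size} too short for window {window_size}, horizon {horizon}"
        )
    idx = np.arange(window_size)[None, :] + np.arange(n_windows)[:, None]
    X = counts[idx]
    y = counts[np.arange(n_windows) + window_size + horizon - 1]
    return WindowedSeries(X=X, y=y, window_size=window_size, horizon=horizon)


def fit_forecaster(train: WindowedSeries, config: FitConfig | None = None) -> FittedLinearModel:
    """Fit the penalized linear autoregression on the lag windows."""
    return fit_linear(train.X, train.y, config)


@dataclass
class ForecastReport:
    """Held-out one-step-ahead forecast summary."""

    evaluation: EvaluationReport
    underpredicted_days: int
    n_train_windows: int
    n_test_windows: int
    model: FittedLinearModel
    actual: np.ndarray
    predicted: np.ndarray
    test_days: np.ndarray

    def to_dict(self) -> dict:
        return {
            "evaluation": self.evaluation.to_dict(),
            "underpredicted_days": self.underpredicted_days,
            "n_train_windows": self.n_train_windows,
            "n_test_windows": self.n_test_windows,
            "model": self.model.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def rolling_evaluate(
    series: TimeSeries,
    window_size: int = 14,
    config: FitConfig | None = None,
    split: float = 0.7,
) -> ForecastReport:
    """Fit on the first ``split`` fraction of windows; predict the rest
    one step ahead without refitting.

    Reports the asymmetric error metrics and the strict count of
    under-predicted days over the held-out span.  Deterministic for fixed
    (series, config).
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must be in (0, 1)")
    windows = make_windows(series, window_size)
    n_train = int(round(split * windows.n_windows))
    if n_train < 1 or windows.n_windows - n_train < 1:
        raise ValueError("not enough windows on both sides of the split")
    train = WindowedSeries(
        X=windows.X[:n_train], y=windows.y[:n_train],
        window_size=window_size, horizon=windows.horizon,
    )
    model = fit_forecaster(train, config)
    X_test, y_test = windows.X[n_train:], windows.y[n_train:]
    y_hat = model.predict(X_test)
    test_days = np.asarray(series.t)[np.arange(n_train, windows.n_windows)
                                     + window_size + windows.horizon - 1]
    return ForecastReport(
        evaluation=evaluate(y_test, y_hat),
        underpredicted_days=count_underpredicted_days(y_test, y_hat),
        n_train_windows=n_train,
        n_test_windows=windows.n_windows - n_train,
        model=model,
        actual=y_test,
        predicted=y_hat,
        test_days=test_days,
    )


def write_predictions_csv(report: ForecastReport, path) -> None:
    """Per-day predictions: day, actual, predicted, residual."""
    pd.DataFrame({
        "day": report.test_days,
        "actual": report.actual,
        "predicted": report.predicted,
        "residual": report.predicted - report.actual,
    }).to_csv(path, index=False, float_format="%.10g")
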