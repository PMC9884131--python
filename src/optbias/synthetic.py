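"""Seeded synthetic data: linear regression sets, epidemic surge series,
and run-to-failure degradation trajectories.

Three regimes are emulated:

* **Linear regression** (:func:`gen_linear`): features i.i.d. uniform on
  [0,1]^d, response linear plus Gaussian noise.  The study conditions are
  n = 1000 instances with 1 or 4 features.
* **Epidemic surge series** (:func:`gen_surge_series`): a daily case-count
  curve built from a baseline plus Gaussian-shaped surge bumps with
  additive noise, clipped at zero — the regime where under-prediction is
  costly.
* **Degradation / remaining-useful-life** (:func:`gen_degradation`):
  per-unit sensor channels drifting linearly over the unit's life toward
  a common failure level, with the per-cycle target RUL = lifetime − cycle
  (linear degradation, no plateau cap by default).

All generators are pure functions of their arguments including the seed,
and every dataset retains its noiseless ``truth`` so tests can recompute
noise-free responses exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "TimeSeries",
    "DegradationSet",
    "LinearGenerator",
    "gen_linear",
    "gen_surge_series",
    "gen_degradation",
    "default_surge_series",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_series_csv",
    "read_series_csv",
    "UNIVARIATE_COEFFS",
    "MULTIVARIATE_COEFFS",
    "DEFAULT_INTERCEPT",
    "DEFAULT_NOISE_SD",
]

# Study-condition defaults for the linear simulations (the slopes span a
# mix of signs and magnitudes so no single feature dominates; noise sd 0.5
# gives r^2 around 0.4-0.8 at n=1000, a realistic signal level).
UNIVARIATE_COEFFS = (2.0,)
MULTIVARIATE_COEFFS = (1.5, -2.0, 1.0, 0.5)
DEFAULT_INTERCEPT = 1.0
DEFAULT_NOISE_SD = 0.5


@dataclass
class Dataset:
    """Feature matrix + target vector, with optional generating truth."""

    X: np.ndarray
    y: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size or self.y.size < 1:
            raise ValueError("X and y must have matching, non-zero length")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in dataset")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def noiseless_response(self, X: np.ndarray | None = None) -> np.ndarray:
        """Recompute the noise-free response from the stored truth."""
        if self.truth is None:
            raise ValueError("dataset carries no truth record")
        X = self.X if X is None else np.atleast_2d(np.asarray(X, dtype=float))
        return X @ np.asarray(self.truth["coefficients"]) + self.truth["intercept"]


@dataclass
class TimeSeries:
    """Daily count series with optional latent (noiseless) curve."""

    t: np.ndarray
    counts: np.ndarray
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t.shape != self.counts.shape:
            raise ValueError("t and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)
            if self.truth.shape != self.counts.shape:
                raise ValueError("truth must match counts length")

    def __len__(self) -> int:
        return self.counts.size


@dataclass
class DegradationSet:
    """Run-to-failure trajectories for several units.

    ``X``/``y`` stack all units' cycle-start sensor readings and RUL
    targets; ``unit_ids`` maps each row to its unit and ``lifetimes``
    records each unit's total life in cycles.
    """

    X: np.ndarray
    y: np.ndarray
    unit_ids: np.ndarray
    lifetimes: np.ndarray
    units: list[Dataset] = field(repr=False, default_factory=list)


def gen_linear(
    n: int,
    d: int,
    coefficients,
    intercept: float,
    noise_sd: float,
    seed: int,
) -> Dataset:
    """Linear data: X ~ U[0,1]^d, y = X·coefficients + intercept + N(0, sd²)."""
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    if n < 1 or d < 1 or coefficients.size != d:
        raise ValueError("need n >= 1 and len(coefficients) == d >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, d))
    y = X @ coefficients + intercept + rng.normal(0.0, noise_sd, size=n)
    return Dataset(
        X=X, y=y,
        truth={"coefficients": coefficients, "intercept": float(intercept),
               "noise_sd": float(noise_sd)},
    )


@dataclass(frozen=True)
class LinearGenerator:
    """Replicate source for the bias-variance protocol: fixed truth,
    fresh noise and features per seed."""

    n: int = 1000
    coefficients: tuple = UNIVARIATE_COEFFS
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = DEFAULT_NOISE_SD

    @property
    def d(self) -> int:
        return len(self.coefficients)

    def sample(self, seed: int) -> Dataset:
        return gen_linear(self.n, self.d, self.coefficients, self.intercept,
                          self.noise_sd, seed)

    def true_response(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ np.asarray(self.coefficients) + self.intercept

    def test_grid(self, n_points: int = 200, seed: int = 12345) -> np.ndarray:
        """Fixed evaluation grid spanning the feature range [0,1]^d."""
        if self.d == 1:
            return np.linspace(0.0, 1.0, n_points)[:, None]
        rng = np.random.default_rng(seed)
        return rng.uniform(0.0, 1.0, size=(n_points, self.d))


# Default two-surge epidemic curve: ~1.5 years of daily counts with a
# moderate first wave and a larger second wave, matching the shape of a
# two-wave outbreak at state scale.
DEFAULT_SURGES = ((150, 400.0, 25.0), (380, 900.0, 35.0))


def gen_surge_series(
    length: int,
    baseline: float,
    surges,
    noise_sd: float,
    seed: int,
) -> TimeSeries:
    """Epidemic-style daily counts: baseline + Gaussian bumps + noise,
    clipped at zero.  Each surge is (peak_day, peak_height, width)."""
    if length < 30:
        raise ValueError("length must be >= 30")
    t = np.arange(length)
    latent = np.full(length, float(baseline))
    for peak_day, peak_height, width in surges:
        if not (0 <= peak_day < length):
            raise ValueError(f"peak_day {peak_day} outside series range")
        if width <= 0:
            raise ValueError("surge width must be > 0")
        latent = latent + peak_height * np.exp(-0.5 * ((t - peak_day) / width) ** 2)
    rng = np.random.default_rng(seed)
    counts = np.maximum(0.0, latent + rng.normal(0.0, noise_sd, size=length))
    return TimeSeries(t=t, counts=counts, truth=latent)


def default_surge_series(seed: int = 0) -> TimeSeries:
    """The packaged two-surge demonstration series (534 days)."""
    return gen_surge_series(length=534, baseline=50.0, surges=DEFAULT_SURGES,
                            noise_sd=30.0, seed=seed)


def gen_degradation(
    n_units: int,
    cycles_range: tuple[int, int] = (128, 362),
    n_sensors: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
    slope_jitter: float = 0.05,
) -> DegradationSet:
    """Run-to-failure sensor trajectories with linear RUL targets.

    Each unit draws a lifetime uniformly from ``cycles_range``.  Sensor
    ``s`` of every unit degrades linearly from a healthy level toward a
    common failure level ``base_s`` reached at end of life:
    ``reading = base_s - slope_{u,s} * RUL + noise`` where the unit slope
    is the sensor's nominal slope perturbed by ``slope_jitter`` (relative).
    Targets are RUL = lifetime − cycle; features are cycle-start readings.
    """
    lo, hi = cycles_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid cycles_range")
    if n_units < 1 or n_sensors < 1:
        raise ValueError("need at least one unit and one sensor")
    rng = np.random.default_rng(seed)
    base = rng.uniform(5.0, 15.0, size=n_sensors)
    nominal_slope = rng.uniform(0.02, 0.08, size=n_sensors)

    units: list[Dataset] = []
    lifetimes = rng.integers(lo, hi + 1, size=n_units)
    for u in range(n_units):
        life = int(lifetimes[u])
        cycles = np.arange(life)
        rul = (life - cycles).astype(float)
        slopes = nominal_slope * (1.0 + slope_jitter * rng.standard_normal(n_sensors))
        clean = base[None, :] - rul[:, None] * slopes[None, :]
        X = clean + rng.normal(0.0, noise_sd, size=clean.shape)
        # exact linear decoder on noiseless readings: rul = (base_1 - x_1)/slope_1
        decoder = np.zeros(n_sensors)
        decoder[0] = -1.0 / slopes[0]
        units.append(Dataset(X=X, y=rul, truth={
            "coefficients": decoder, "intercept": float(base[0] / slopes[0]),
            "noise_sd": float(noise_sd),
        }))
    X_all = np.vstack([u.X for u in units])
    y_all = np.concatenate([u.y for u in units])
    ids = np.concatenate([np.full(len(u.y), i) for i, u in enumerate(units)])
    return DegradationSet(X=X_all, y=y_all, unit_ids=ids,
                          lifetimes=np.asarray(lifetimes), units=units)


# ---------------------------------------------------------------------------
# CSV round-trip (comma separator, header row, UTF-8)

def write_dataset_csv(dataset: Dataset, path) -> None:
    """Write features as x1..xd plus a final ``y`` column."""
    cols = {f"x{j + 1}": dataset.X[:, j] for j in range(dataset.d)}
    cols["y"] = dataset.y
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_dataset_csv(path) -> Dataset:
    df = pd.read_csv(path)
    if "y" not in df.columns:
        raise ValueError(f"{Path(path).name}: expected a 'y' column")
    y = df["y"].to_numpy(dtype=float)
    X = df.drop(columns="y").to_numpy(dtype=float)
    return Dataset(X=X, y=y)


def write_series_csv(series: TimeSeries, path) -> None:
    pd.DataFrame({"day": series.t, "count": series.counts}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_series_csv(path) -> TimeSeries:
    df = pd.read_csv(path)
    for col in ("day", "count"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: expected columns day,count")
    return TimeSeries(t=df["day"].to_numpy(dtype=int),
                      counts=df["count"].to_numpy(dtype=float))
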