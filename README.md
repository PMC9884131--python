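# optbias — one-sided (optimism-bias) regularization for regression

Standard regression losses treat over- and under-predictions
symmetrically, but in many applications one side of the error is far
more costly: under-predicting daily epidemic case counts leaves
hospitals unprepared for a surge, and over-estimating the remaining
useful life (RUL) of a machine delays maintenance past failure.
`optbias` implements a simple convex regularizer that lets any convex
regression model trade a little overall accuracy for direct control of
how often — and how badly — it errs on the costly side.

## The penalty

For a model h(x) = W·Φ(x) + b with signed residuals eᵢ = h(Xᵢ) − yᵢ
(positive = over-prediction), the one-sided penalty is

    Ψ_over(h)  = Σᵢ (sgn(eᵢ) + 1) · |eᵢ|ᵖ      (penalize over-predictions)
    Ψ_under(h) = Σᵢ (−sgn(eᵢ) + 1) · |eᵢ|ᵖ     (penalize under-predictions)

and the training objective becomes

    min_{W,b}  L̂(y, h(X)) + (β/2) · Ψ(h(X)),

optionally alongside classical ℓ₁/ℓ₂ terms λ·P(W).  Residuals on the
penalized side count twice their |e|ᵖ; the other side contributes
nothing.  For β ≥ 0 and p ≥ 1 the penalty is convex, so the regularized
objective inherits (strict) convexity from the base loss and the global
minimum exists.  The package uses p = 2 by default.

Provided on top of the penalty mathematics (`optbias.penalty`):

* `fit_linear` — penalized linear regression (quasi-Newton on the smooth
  convex objective),
* `fit_svr` — ε-insensitive support-vector regression in the primal with
  the added penalty (linear and RBF kernels),
* `make_loss_plugin` — the penalized loss and its prediction-space
  gradient as plain callables for externally trained models,
* `evaluate` — asymmetric metrics: MSE, mean squared positive/negative
  error (MSPE/MSNE), over/under-prediction counts and rates,
* `bias_variance_estimate` / `run_beta_sweep` — the replicate simulation
  harness behind the bias–variance story,
* seeded synthetic generators for linear data, two-surge epidemic
  series, and run-to-failure degradation trajectories,
* a rolling surge forecaster and a thin `optbias` command line
  (`simulate`, `fit`, `sweep`, `forecast`, `evaluate`).

## Worked example

Penalizing under-predictions while forecasting a synthetic two-surge
epidemic series (534 days, 14-day windows, last 30 % held out):

```python
from optbias import FitConfig, PenaltyConfig, default_surge_series, rolling_evaluate

series = default_surge_series(seed=3)
for beta in [0.0, 1.0]:
    cfg = FitConfig(penalty=PenaltyConfig(direction="under", p=2, beta=beta))
    rep = rolling_evaluate(series, window_size=14, config=cfg, split=0.7)
    print(beta, rep.underpredicted_days, rep.n_test_windows,
          round(rep.evaluation.mse), round(rep.evaluation.msne))
```

prints

```
0.0 61 156 928 757
1.0 45 156 1126 603
```

At β = 0 the ordinary least-squares forecaster lands below the actual
count on 61 of 156 held-out days.  With the under-prediction penalty at
β = 1 that drops to 45 days and the squared error on the under-predicted
side (MSNE) falls from 757 to 603, while total MSE rises from 928 to
1126 — the deliberate price of sitting above the noise during surges.
The same mechanism cuts the over-estimation rate of an RBF SVR on
synthetic run-to-failure data from about 0.50 to about 0.21
(`examples/05_degradation_svr.py`).

More narrative scripts live in `examples/` — penalty basics, the β
effect on a linear fit, the replicate β-sweep, surge forecasting, and
RUL over-estimation control.

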