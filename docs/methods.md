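# Methods

## The one-sided penalty

With signed residuals e = h(X) − y, the penalty applied to direction
"over" is Ψ(e) = Σᵢ (sgn(eᵢ)+1)·|eᵢ|ᵖ and to "under"
Σᵢ (−sgn(eᵢ)+1)·|eᵢ|ᵖ.  The weight (sgn(e)+1) is 2 on the penalized
side, 0 on the other side, and 1 at e = 0 — where |e|ᵖ = 0 anyway for
p ≥ 1, so the sgn(0) := 0 tie-break is inert.  |e|ᵖ (rather than a
signed power) keeps Ψ well defined for odd p.  Each summand is convex
(a non-negative multiple of a convex function on each half-line,
continuous at 0), so Ψ is convex for β ≥ 0, p ≥ 1, and adding (β/2)Ψ to
a strictly convex base loss keeps the objective strictly convex — the
property the numerical midpoint-convexity probe in the tests verifies
on random parameter pairs with absolute slack 1e−9 (floating-point
noise on well-scaled costs).

**Normalization.** Ψ as written is a raw sum while the squared-error
base loss carries 1/n.  `PenaltyConfig` therefore defaults to
`normalization="mean"` (Ψ/n) so one β works across sample sizes and
matches the 1/n-scaled linear loss; `normalization="sum"` is available
and is the natural pairing for the SVR objective, which is itself an
un-normalized sum (with "mean" the penalty is diluted by 1/n against
the C-weighted hinge sum and barely acts).  The SVR examples and tests
use the sum form for that reason.

**Gradient.** On the penalized side the summand derivative is
2p·|e|^(p−1)·sgn(e); on the other side 0; at e = 0 the subgradient
element 0 is chosen, which leaves the unpenalized side exactly
untouched and is the true derivative for p > 1.  For p = 1 the returned
vector is a valid subgradient.

**Sign convention.** Positive residual ⇔ prediction above actual
(over-prediction), everywhere: penalty, metrics, forecaster.  "Mean
squared positive error" (MSPE) is the mean of e² over e > 0.  This
fixed convention implies that penalizing over-predictions shrinks MSPE
and grows MSNE; descriptions of the effect direction in parts of the
literature are ambiguous about which sign "positive error" refers to,
so the package documents and uses exactly one convention.

## Estimators

**Linear.** Objective mean((h−y)²) + (β/2)Ψ + λ₂‖W‖² + λ₁‖W‖₁, Φ =
identity.  For p = 2 the objective is C¹ (the one-sided quadratic has a
continuous derivative at 0), so L-BFGS-B with analytic gradients
applies; λ₁ is handled by subgradient (sign(W)).  Initialization is
W = 0, b = mean(y): deterministic and scale-reasonable for a convex
problem.  Convergence is declared when the final gradient norm is at or
below tolerance (default 1e−8; up to 1e−6 is still reported as
converged since L-BFGS terminates on its own projected-gradient and
function-decrease criteria); non-convergence is reported in the
`converged` flag, never raised.  The intercept is never penalized by
λ·P(W).

**SVR.** The constrained slack formulation
min ½‖ω‖² + C·Σ(ξ⁺+ξ⁻) s.t. |h(Xᵢ)−yᵢ| ≤ ε+ξ is solved as its
unconstrained equivalent ½‖ω‖² + C·Σ max(0, |eᵢ|−ε) + (β/2)Ψ — the
added penalty breaks the standard dual derivation, so the primal is the
natural formulation.  The hinge is softplus-smoothed with width
μ = 1e−6 so quasi-Newton iteration applies; the smoothing error in the
objective is below 2·C·n·μ·ln 2 (≈ 1e−4 at C = 10, n ≈ 400), well
inside the cross-solver comparison tolerance.  For the RBF kernel the
model is parameterized by per-training-point coefficients α with
‖ω‖² = αᵀKα; γ defaults to 1/d.  b is not part of ‖ω‖².  Defaults
C = 1, ε = 0.1 are generic; the RUL demonstration uses C = 10, ε = 5,
the scale appropriate for targets in cycles.  For strongly non-smooth
instances the solver may stop on its iteration cap with the optimality
gap already far below the reporting precision; `converged` then records
the honest gradient-norm status.

**Loss plug-in.** `make_loss_plugin` returns (value, gradient) closures
computing MSE + (β/2)Ψ and its prediction-space gradient, the contract
an externally trained model needs.  Mutual consistency is checked
against central finite differences in the tests.

## Evaluation protocol

`evaluate` reports MSE, MSPE, MSNE, side counts/rates and r².  Exact
identities maintained: n·MSE = n_over·MSPE + n_under·MSNE, and the side
counts partition n.  An empty side reports 0 with count 0 (no NaNs in
sweep tables); zero-variance targets flag r² as undefined instead of
raising.

`bias_variance_estimate` fits the model on replicate datasets drawn
from a fixed truth, then at each point of a fixed test grid computes
the across-replicate prediction variance and the squared gap between
the mean prediction and the noiseless truth, averaging both over the
grid.  The grid is 200 points spanning the generator's feature range
(a linspace for d = 1, uniform draws under a fixed internal seed for
d > 1).  Bias is reported squared; per-replicate predictions and r²
are retained so un-squared summaries can be derived.  Replicate r² is
computed on each replicate's own training data.

## Synthetic data — what it emulates and what it does not

The generators reproduce the *conditions* of the method's simulation
studies, not any real dataset:

* `gen_linear` — X i.i.d. uniform on [0,1]^d, y linear + Gaussian
  noise.  Study conditions: n = 1000, d ∈ {1, 4}, 100 replicates.
  Defaults chosen once as realistic: univariate slope 2.0, multivariate
  slopes (1.5, −2.0, 1.0, 0.5), intercept 1.0, noise sd 0.5 (r² ≈ 0.6
  univariate).  Uniform features keep scales bounded so one β grid is
  comparable across settings.
* `gen_surge_series` — baseline + Gaussian-shaped surge bumps + noise,
  clipped at 0.  The packaged default is 534 days, baseline 50, surges
  at days 150 (height 400, width 25) and 380 (height 900, width 35),
  noise sd 30 — a two-wave outbreak shape at state scale.  These bumps
  are a shape surrogate, not an epidemic mechanism: no reporting
  artifacts, day-of-week effects, or overdispersed counts.  Passing
  tests show the loss behaves as intended on surge-shaped series, not
  that any real surveillance series is forecast accurately.
* `gen_degradation` — per-unit lifetimes uniform on (128, 362) cycles;
  each sensor drifts linearly from a healthy level to a common failure
  level reached at end of life (reading = base − slope·RUL + noise,
  slope jittered 5 % per unit), target RUL = lifetime − cycle with no
  capping plateau (capping is deliberately left out of the default).
  RUL is exactly linearly decodable from noiseless readings only within
  a unit (or when lifetimes are degenerate); across units the small
  slope jitter makes decoding approximate, which is what makes the
  regression problem non-trivial.

All generators are pure functions of their arguments including the
seed, and retain the noiseless truth.

## Forecasting demonstration

The forecaster is a windowed linear autoregression (default window 14
days, horizon 1, 70/30 train/test split, one-step-ahead prediction
without refitting): the claim under test is the loss term's effect, not
any architecture, and the plug-in contract leaves the door open for
recurrent models.  Windows never contain their target
(structurally asserted), and β = 0 reduces to plain windowed least
squares.

## Sweep harness

`run_beta_sweep` derives replicate seeds from the master seed alone, so
the same replicate datasets are reused at every β: the β axis is a
paired comparison, the grid can be extended without disturbing earlier
replicates, and the monotone trends (bias² non-decreasing, mean r²
non-increasing, penalized side shrinking) are not blurred by
Monte-Carlo noise between grid points.  Default grid
{0, 0.01, 0.1, 1, 10}.  CSV output is fixed at 10 significant digits so
identical config + seed reproduce byte-identical files.

A β-monotonicity note: at the optimum the penalty value Ψ is provably
non-increasing in β (compare the optimality of the β₁ and β₂ solutions
and add the inequalities), hence so is the penalized-side sum of squared
residuals at p = 2; the penalized-side *count* and the conditional MSPE
are only empirically monotone, which holds across the tested
configurations.

## Problem sizes

Test and demonstration sizes are the package's own defaults: 100
replicates of n = 1000 for the sweep protocol; 1000 random parameter
pairs per β for the convexity probe; 100 residual vectors for gradient
checks; a 534-day series for forecasting; 8 units (trajectories thinned
4×) for the RUL demonstration.  The complete suite runs in well under a
minute on one CPU.

## Known limitations

* The penalty controls the training-side residual distribution; the
  held-out effect follows only insofar as train and test distributions
  match, as in the synthetic studies.
* No automatic β selection: choose β by sweeping (the harness exists
  for exactly that) against the application's asymmetric cost.
* For p = 1 the objective is non-smooth at e = 0 and the quasi-Newton
  path relies on subgradients; p = 2 is the supported default.
* The SVR solver is a smoothed-primal method adequate at these problem
  sizes; it is not tuned for n ≫ 10⁴.
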