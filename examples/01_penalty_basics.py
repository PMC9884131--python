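"""The one-sided penalty on a small residual vector.

Builds a vector of signed residuals (prediction - actual), evaluates the
penalty in both directions, and shows that the gradient is zero on the
unpenalized side.
"""

import numpy as np

from optbias import PenaltyConfig, psi, psi_gradient, signed_residuals, total_cost

predictions = np.array([2.5, 4.0, 1.0, 7.0])
actuals = np.array([2.0, 5.0, 1.0, 4.0])
e = signed_residuals(predictions, actuals)
print("signed residuals (pred - actual):", e)

over = PenaltyConfig(direction="over", p=2, beta=1.0, normalization="mean")
under = PenaltyConfig(direction="under", p=2, beta=1.0, normalization="mean")
print("Psi penalizing over-predictions :", psi(e, over))
print("Psi penalizing under-predictions:", psi(e, under))
print("gradient (over direction)       :", psi_gradient(e, over))

mse = float(np.mean(e**2))
print("total cost = MSE + (beta/2)*Psi :", total_cost(mse, e, over))

# Entries 0.5 and 3.0 are over-predictions: only they enter the "over"
# penalty (each with weight 2), and the gradient vanishes where e <= 0.
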