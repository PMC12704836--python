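"""Fit the Freundlich isotherm Qe = K * Ce^(1/n) to noisy batch data.

Simulates a 10-point batch-equilibrium experiment at 5% multiplicative
noise for a compound with K = 100, 1/n = 0.5, then recovers the
parameters with both estimators.
"""

import numpy as np

from freundlich_qsar import fit_freundlich, generate_isotherm_data, predict_qe

true_K, true_n = 100.0, 0.5
ce = np.geomspace(0.5, 20.0, 10)
data = generate_isotherm_data(true_K, true_n, ce, noise_cv=0.05, seed=42)

for method in ("loglinear", "nonlinear"):
    fit = fit_freundlich(data, method)
    print(
        f"{method:9s}  K = {fit.K:7.2f}  (true {true_K})   "
        f"1/n = {fit.one_over_n:.4f}  (true {true_n})   "
        f"r2(log-log) = {fit.r_squared_loglog:.4f}"
    )

fit = fit_freundlich(data)
print(f"predicted Qe at Ce = 4 mg/L: {predict_qe(fit, 4.0):.1f} mg/g "
      f"(noise-free value {true_K * 4**true_n:.1f})")

# The loglinear fit weights relative errors (matching the multiplicative
# noise here); the nonlinear fit weights absolute errors.  Both land
# within a few percent of the true parameters at this noise level.
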