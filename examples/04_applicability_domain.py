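"""Williams-plot applicability domain for a fitted QSAR model.

Every compound is placed at (leverage, standardized residual); the
alert leverage h* = 3(m+1)/n and the |sigma| < 3 band delimit the
region where predictions are structurally trustworthy.
"""

import numpy as np

from freundlich_qsar import (
    SyntheticSpec,
    fit_ols,
    generate_descriptor_matrix,
    generate_linear_response,
    williams_report,
)

beta = {"E_LUMO": 9.0, "Fukui(-)_max": -4.5, "Wiberg(C-C)_min": 0.6}
spec = SyntheticSpec(n_compounds=38, beta=beta, intercept=1.0,
                     noise_sd=0.05, seed=5)
X = generate_descriptor_matrix(spec)
y = generate_linear_response(X, spec)
model = fit_ols(X, y, list(beta))

# an external "compound" far outside the training descriptor ranges
X_out = generate_descriptor_matrix(
    SyntheticSpec(n_compounds=2, seed=6)
)
X_out.df.iloc[0] = X.df.mean()                 # at the training centroid
X_out.df.iloc[1] = X.df.max() + 5 * (X.df.max() - X.df.min())  # far outside

rep = williams_report(model, X, y, X_out, np.array([y.mean(), y.mean()]))
print(f"m = {rep.m} predictors, n = {rep.n_train} training compounds")
print(f"alert leverage h* = {rep.h_star:.4f}")
print(rep.table.tail(4).to_string(index=False))
n_in = int(rep.in_domain().sum())
print(f"\nin-domain compounds: {n_in}/{len(rep.table)}")

# The centroid query sits at the minimum leverage 1/n and is in-domain;
# the extrapolated query exceeds h* and is flagged high-leverage.
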