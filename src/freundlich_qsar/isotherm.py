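"""Freundlich isotherm fitting and prediction.

The Freundlich isotherm Qe = K * Ce^(1/n) is the empirical workhorse for
adsorption on heterogeneous surfaces such as activated carbon: Qe is the
adsorbed amount at equilibrium (mg/g), Ce the equilibrium concentration
(mg/L), K the capacity-like constant and 1/n the adsorption index
measuring nonlinearity.  Two estimators are provided:

* ``loglinear`` — OLS of ln Qe on ln Ce; K = exp(intercept), 1/n = slope.
  The classical linearization; errors are effectively multiplicative.
* ``nonlinear`` — least squares on the original Qe scale, initialized
  from the loglinear fit.

On noiseless data the two agree; on noisy data they weight errors
differently and both are exposed because the upstream literature rarely
states which one produced a published (K, 1/n) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

__all__ = ["IsothermData", "FreundlichFit", "fit_freundlich", "predict_qe"]


@dataclass(frozen=True)
class IsothermData:
    """Paired batch-equilibrium measurements (Ce mg/L, Qe mg/g)."""

    Ce: np.ndarray
    Qe: np.ndarray

    def __post_init__(self) -> None:
        ce = np.asarray(self.Ce, dtype=float)
        qe = np.asarray(self.Qe, dtype=float)
        if ce.shape != qe.shape or ce.ndim != 1:
            raise ValueError("Ce and Qe must be 1-D and equal length")
        if np.any(ce <= 0) or np.any(qe <= 0):
            raise ValueError("Ce and Qe must be strictly positive")
        object.__setattr__(self, "Ce", ce)
        object.__setattr__(self, "Qe", qe)

    def __len__(self) -> int:
        return len(self.Ce)


@dataclass(frozen=True)
class FreundlichFit:
    K: float
    one_over_n: float
    r_squared_loglog: float
    method: Literal["loglinear", "nonlinear"]
    # loglinear parameters used to initialize a nonlinear fit
    init: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("fitted K must be positive")


def fit_freundlich(
    data: IsothermData,
    method: Literal["loglinear", "nonlinear"] = "loglinear",
) -> FreundlichFit:
    """Estimate (K, 1/n) from batch-equilibrium data.

    Natural logs are used for the linearization (the base only shifts
    the intercept's meaning, not K or 1/n).
    """
    if len(data) < 3:
        raise ValueError("need at least 3 (Ce, Qe) points")
    if np.ptp(data.Ce) == 0:
        raise ValueError("degenerate data: all Ce equal")
    ln_ce = np.log(data.Ce)
    ln_qe = np.log(data.Qe)
    res = stats.linregress(ln_ce, ln_qe)
    k_ll = float(np.exp(res.intercept))
    n_ll = float(res.slope)
    r2 = float(res.rvalue**2)
    if method == "loglinear":
        return FreundlichFit(k_ll, n_ll, r2, "loglinear")
    if method != "nonlinear":
        raise ValueError(f"unknown method {method!r}")

    def model(ce, k, n):
        return k * ce**n

    popt, _ = optimize.curve_fit(
        model, data.Ce, data.Qe, p0=[k_ll, n_ll], maxfev=10_000
    )
    return FreundlichFit(
        float(popt[0]), float(popt[1]), r2, "nonlinear", init=(k_ll, n_ll)
    )


def predict_qe(fit: FreundlichFit, Ce: np.ndarray | float) -> np.ndarray:
    """Elementwise Qe = K * Ce^(1/n)."""
    ce = np.asarray(Ce, dtype=float)
    if np.any(ce <= 0):
        raise ValueError("Ce must be strictly positive")
    return fit.K * ce**fit.one_over_n
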