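"""Applicability-domain analysis via the Williams plot.

A QSAR prediction is only trusted inside the model's structural domain.
The Williams plot places every compound at (leverage h_i, standardized
residual sigma_i): h_i = x_i (X^T X)^{-1} x_i^T (intercept-augmented row
against the training design) measures distance from the training
centroid in descriptor space, and sigma_i is the residual divided by the
root-mean-square training residual sqrt(sum e_j^2 / (n-1)).  A compound
is flagged out of domain when h_i reaches the alert leverage
h* = 3(m+1)/n or when |sigma_i| exceeds 3.

Test-set residuals are standardized by the *training* residual scale so
both sets share one plot; boundary conventions (>= for h*, strict > 3
for sigma) are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_io import DescriptorMatrix
from .model_build import ModelFit, _design, apply_transform

__all__ = [
    "ADReport",
    "standardized_residuals",
    "leverages",
    "alert_leverage",
    "williams_report",
]


def residual_scale(residuals: np.ndarray, n_train: int) -> float:
    """Root-mean-square residual scale sqrt(sum e^2 / (n_train - 1))."""
    if n_train < 2:
        raise ValueError("need n_train >= 2")
    return float(np.sqrt(np.sum(np.asarray(residuals) ** 2) / (n_train - 1)))


def standardized_residuals(
    y: np.ndarray,
    y_hat: np.ndarray,
    n_train: int | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """Residuals divided by the RMS residual scale.

    With ``scale`` unset the scale is computed from the given residuals
    themselves using ``n_train`` (defaulting to their length).  Zero
    residual variance yields all-zero sigmas by convention.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    resid = y - y_hat
    if scale is None:
        n = n_train if n_train is not None else len(resid)
        scale = residual_scale(resid, n)
    if scale == 0.0:
        return np.zeros_like(resid)
    return resid / scale


def leverages(
    X_train: DescriptorMatrix,
    subset: Sequence[str],
    X_query: DescriptorMatrix | None = None,
) -> np.ndarray:
    """h_i = x_i (X^T X)^{-1} x_i^T with intercept-augmented rows.

    ``X_query`` defaults to the training matrix itself (self-leverages);
    external compounds may fall outside (0, 1].
    """
    Xd = _design(X_train, subset)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient training design")
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    Q = Xd if X_query is None else _design(X_query, subset)
    return np.einsum("ij,jk,ik->i", Q, xtx_inv, Q)


def alert_leverage(m: int, n_train: int) -> float:
    """h* = 3(m+1)/n for m predictors and n training compounds."""
    if m < 1:
        raise ValueError("need at least one predictor")
    if n_train <= m + 1:
        raise ValueError("need n_train > m + 1")
    return 3.0 * (m + 1) / n_train


@dataclass(frozen=True)
class ADReport:
    """Williams-plot table with domain flags.

    ``table`` columns: name, set (train/test), leverage, std_residual,
    high_leverage, outlier.  Flags are pure functions of (sigma, h, h*)
    under the stated boundary conventions, so they can be recomputed
    from the table alone.
    """

    table: pd.DataFrame
    h_star: float
    m: int
    n_train: int
    sigma_limit: float = 3.0
    leverage_boundary_is_high: bool = True  # h == h* counts as high
    sigma_boundary_is_outlier: bool = False  # |sigma| == limit stays in range

    def in_domain(self) -> pd.Series:
        return ~(self.table["high_leverage"] | self.table["outlier"])

    def to_dict(self) -> dict:
        return {
            "h_star": self.h_star,
            "m": self.m,
            "n_train": self.n_train,
            "sigma_limit": self.sigma_limit,
            "table": self.table.to_dict(orient="list"),
        }


def _flags(
    h: np.ndarray,
    sigma: np.ndarray,
    h_star: float,
    sigma_limit: float,
    leverage_boundary_is_high: bool,
    sigma_boundary_is_outlier: bool,
) -> tuple[np.ndarray, np.ndarray]:
    high = h >= h_star if leverage_boundary_is_high else h > h_star
    out = (
        np.abs(sigma) >= sigma_limit
        if sigma_boundary_is_outlier
        else np.abs(sigma) > sigma_limit
    )
    return high, out


def williams_report(
    model: ModelFit,
    X_train: DescriptorMatrix,
    y_train: np.ndarray,
    X_test: DescriptorMatrix | None = None,
    y_test: np.ndarray | None = None,
    sigma_limit: float = 3.0,
    leverage_boundary_is_high: bool = True,
    sigma_boundary_is_outlier: bool = False,
) -> ADReport:
    """Full applicability-domain table for training (and test) compounds."""
    subset = model.descriptor_names
    yt_train = apply_transform(y_train, model.response_transform)
    pred_train = model.predict(X_train)
    resid_train = yt_train - pred_train
    scale = residual_scale(resid_train, len(resid_train))
    h_train = leverages(X_train, subset)
    trace = float(h_train.sum())
    if abs(trace - (model.p + 1)) > 1e-6 * max(1.0, model.p + 1):
        raise AssertionError(
            f"hat-matrix trace {trace:.6f} != m+1 = {model.p + 1}"
        )
    sigma_train = standardized_residuals(yt_train, pred_train, scale=scale)

    names = list(X_train.compound_names)
    sets = ["train"] * len(names)
    h_all = [h_train]
    sigma_all = [sigma_train]
    if X_test is not None and X_test.shape[0] > 0:
        if y_test is None:
            raise ValueError("y_test required when X_test is given")
        yt_test = apply_transform(y_test, model.response_transform)
        pred_test = model.predict(X_test)
        h_all.append(leverages(X_train, subset, X_test))
        sigma_all.append(
            standardized_residuals(yt_test, pred_test, scale=scale)
        )
        names += list(X_test.compound_names)
        sets += ["test"] * X_test.shape[0]

    h = np.concatenate(h_all)
    sigma = np.concatenate(sigma_all)
    h_star = alert_leverage(model.p, len(resid_train))
    high, out = _flags(
        h, sigma, h_star, sigma_limit,
        leverage_boundary_is_high, sigma_boundary_is_outlier,
    )
    table = pd.DataFrame(
        {
            "name": names,
            "set": sets,
            "leverage": h,
            "std_residual": sigma,
            "high_leverage": high,
            "outlier": out,
        }
    )
    return ADReport(
        table=table,
        h_star=h_star,
        m=model.p,
        n_train=len(resid_train),
        sigma_limit=sigma_limit,
        leverage_boundary_is_high=leverage_boundary_is_high,
        sigma_boundary_is_outlier=sigma_boundary_is_outlier,
    )
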