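"""Correlation screening and forward-stepwise OLS model building.

The QSAR side of the workflow: screen each quantum-chemical descriptor
against the response (Pearson r), then grow a ladder of nested ordinary
least squares models by forward selection, reporting for every rung the
training-fit statistics customary in QSAR software (R^2, adjusted R^2,
standard error of estimate SD, F and its significance, Friedman
lack-of-fit LOF, RMSE/MAE/RSS on the training set).

The response may be modelled on an identity, log10 or sqrt scale.  The
Freundlich constant K spans nearly four decades across the study
compounds, so a variance-stabilizing transform is usually warranted; the
choice is always explicit and recorded in the fit, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataset_io import DescriptorMatrix

__all__ = [
    "FitMetrics",
    "ModelFit",
    "CorrelationScreen",
    "apply_transform",
    "correlation_screen",
    "fit_ols",
    "stepwise_ladder",
]

Transform = Literal["identity", "log10", "sqrt"]


def apply_transform(y: np.ndarray, transform: Transform) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if transform == "identity":
        return y
    if transform == "log10":
        if np.any(y <= 0):
            raise ValueError("log10 transform requires positive responses")
        return np.log10(y)
    if transform == "sqrt":
        if np.any(y < 0):
            raise ValueError("sqrt transform requires non-negative responses")
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class FitMetrics:
    """Training-fit statistics for one OLS rung.

    LOF is the Friedman lack-of-fit score
    (RSS/n) / (1 - (c + d*p)/n)^2 with c = p + 1 basis functions and
    smoothing parameter d (default 0.5), the form used by the
    GFA/QSAR model-building lineage.
    """

    r_squared: float
    r_squared_adj: float
    sd: float
    f_stat: float
    sig: float
    lof: float
    rmse_tr: float
    mae_tr: float
    rss_tr: float

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "sd": self.sd,
            "f_stat": self.f_stat,
            "sig": self.sig,
            "lof": self.lof,
            "rmse_tr": self.rmse_tr,
            "mae_tr": self.mae_tr,
            "rss_tr": self.rss_tr,
        }


@dataclass(frozen=True)
class ModelFit:
    """A fitted linear QSAR model on the (possibly transformed) response."""

    response_name: str
    response_transform: Transform
    descriptor_names: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    intercept_se: float
    fitted_values: np.ndarray
    residuals: np.ndarray
    n_train: int
    metrics: FitMetrics

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def predict(self, X: DescriptorMatrix) -> np.ndarray:
        """Predictions on the model (transformed-response) scale."""
        cols = X.columns(self.descriptor_names)
        beta = np.array([self.coefficients[n] for n in self.descriptor_names])
        return self.intercept + cols @ beta

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "response_transform": self.response_transform,
            "descriptor_names": list(self.descriptor_names),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "std_errors": dict(self.std_errors),
            "intercept_se": self.intercept_se,
            "n_train": self.n_train,
            "metrics": self.metrics.to_dict(),
        }


@dataclass(frozen=True)
class CorrelationScreen:
    """Per-descriptor Pearson correlation with the response, ranked by |r|."""

    table: pd.DataFrame  # columns: descriptor, r, constant (bool)

    def r(self, descriptor: str) -> float:
        row = self.table[self.table["descriptor"] == descriptor]
        if row.empty:
            raise KeyError(descriptor)
        return float(row["r"].iloc[0])

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)


def correlation_screen(X: DescriptorMatrix, y: np.ndarray) -> CorrelationScreen:
    """Pearson r of every descriptor column with the response.

    Constant columns get r = 0 and a flag rather than a NaN.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError(
            f"descriptor rows ({X.shape[0]}) != response length ({len(y)})"
        )
    if len(y) < 3:
        raise ValueError("need at least 3 compounds for a correlation screen")
    rows = []
    for name in X.descriptor_names:
        col = X.df[name].to_numpy(dtype=float)
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            rows.append((name, 0.0, True))
        else:
            r = float(np.corrcoef(col, y)[0, 1])
            rows.append((name, r, False))
    table = pd.DataFrame(rows, columns=["descriptor", "r", "constant"])
    table = table.reindex(
        table["r"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    return CorrelationScreen(table)


def _design(X: DescriptorMatrix, subset: Sequence[str]) -> np.ndarray:
    """Intercept-augmented design matrix for a descriptor subset."""
    cols = X.columns(subset)
    return np.column_stack([np.ones(cols.shape[0]), cols])


def _ols_core(Xd: np.ndarray, y: np.ndarray):
    """Least-squares on an explicit design: (beta, fitted, resid, rss).

    Fast path used inside stepwise/resampling loops; the public
    ``fit_ols`` goes through statsmodels and is cross-checked against a
    normal-equations oracle in the test suite.
    """
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < Xd.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    fitted = Xd @ beta
    resid = y - fitted
    return beta, fitted, resid, float(resid @ resid)


def friedman_lof(rss: float, n: int, p: int, d: float = 0.5) -> float:
    c = p + 1
    denom = 1.0 - (c + d * p) / n
    if denom <= 0:
        return float("inf")
    return (rss / n) / denom**2


def fit_ols(
    X: DescriptorMatrix,
    y: np.ndarray,
    subset: Sequence[str],
    transform: Transform = "identity",
    response_name: str = "y",
    lof_d: float = 0.5,
) -> ModelFit:
    """OLS of the (transformed) response on a descriptor subset.

    Raises on an exactly collinear design, naming the offending columns.
    A constant response is fit as its mean with R^2 := 0 and F := 0 (the
    0/0 convention).
    """
    subset = list(subset)
    if not subset:
        raise ValueError("descriptor subset must be non-empty")
    yt = apply_transform(y, transform)
    n, p = len(yt), len(subset)
    if X.shape[0] != n:
        raise ValueError("descriptor rows and response length differ")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    Xd = _design(X, subset)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        # identify a minimal set of dependent columns for the error message
        bad = []
        for j, name in enumerate(subset):
            sub = np.delete(Xd, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(Xd):
                bad.append(name)
        raise np.linalg.LinAlgError(
            f"singular design; collinear descriptors: {bad or subset}"
        )

    res = sm.OLS(yt, Xd).fit()
    beta = np.asarray(res.params, dtype=float)
    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = yt - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((yt - yt.mean()) ** 2))

    if tss == 0.0:
        r2, f_stat, sig = 0.0, 0.0, 1.0
    else:
        r2 = 1.0 - rss / tss
        f_stat = ((tss - rss) / p) / (rss / (n - p - 1)) if rss > 0 else float("inf")
        sig = float(stats.f.sf(f_stat, p, n - p - 1)) if np.isfinite(f_stat) else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if tss == 0.0:
        r2_adj = 0.0
    metrics = FitMetrics(
        r_squared=r2,
        r_squared_adj=r2_adj,
        sd=float(np.sqrt(rss / (n - p - 1))),
        f_stat=f_stat,
        sig=sig,
        lof=friedman_lof(rss, n, p, lof_d),
        rmse_tr=float(np.sqrt(rss / n)),
        mae_tr=float(np.mean(np.abs(resid))),
        rss_tr=rss,
    )
    bse = np.asarray(res.bse, dtype=float)
    return ModelFit(
        response_name=response_name,
        response_transform=transform,
        descriptor_names=tuple(subset),
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(subset, beta[1:])},
        std_errors={nm: float(s) for nm, s in zip(subset, bse[1:])},
        intercept_se=float(bse[0]),
        fitted_values=fitted,
        residuals=resid,
        n_train=n,
        metrics=metrics,
    )


def _q2_loo_from_design(Xd: np.ndarray, y: np.ndarray) -> float:
    """Hat-matrix leave-one-out Q^2 on an explicit design."""
    _, _, resid, _ = _ols_core(Xd, y)
    q, _ = np.linalg.qr(Xd)
    h = np.sum(q * q, axis=1)
    if np.any(h >= 1.0 - 1e-12):
        return -np.inf
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    return 1.0 - press / tss


def stepwise_ladder(
    X: DescriptorMatrix,
    y: np.ndarray,
    max_size: int,
    transform: Transform = "identity",
    criterion: Literal["r2", "q2loo"] = "r2",
    response_name: str = "y",
    lof_d: float = 0.5,
) -> list[ModelFit]:
    """Forward-selection ladder of nested OLS models, sizes 1..max_size.

    At each step the descriptor that maximizes the criterion (training
    R^2 or leave-one-out Q^2) joins the model; ties break
    lexicographically by descriptor name.  Candidates whose addition
    makes the design singular are skipped.  Each rung carries full
    training metrics, and by construction RSS is non-increasing and R^2
    non-decreasing along the ladder.
    """
    yt = apply_transform(y, transform)
    n = len(yt)
    names = sorted(X.descriptor_names)
    if max_size > len(names):
        raise ValueError(
            f"max_size ({max_size}) exceeds available descriptors ({len(names)})"
        )
    if max_size >= n - 1:
        raise ValueError("max_size must be < n_train - 1")

    selected: list[str] = []
    ladder: list[ModelFit] = []
    for _ in range(max_size):
        best_name, best_score = None, -np.inf
        for cand in names:  # lexicographic order => deterministic ties
            if cand in selected:
                continue
            trial = selected + [cand]
            Xd = _design(X, trial)
            try:
                if criterion == "r2":
                    _, _, _, rss = _ols_core(Xd, yt)
                    score = -rss
                elif criterion == "q2loo":
                    score = _q2_loo_from_design(Xd, yt)
                else:
                    raise ValueError(f"unknown criterion {criterion!r}")
            except np.linalg.LinAlgError:
                continue
            if score > best_score + 1e-15:
                best_name, best_score = cand, score
        if best_name is None:
            break
        selected.append(best_name)
        # selection order is kept, mirroring nested model tables where
        # each rung appends one variable
        ladder.append(
            fit_ols(X, y, list(selected), transform, response_name, lof_d)
        )
    _assert_nested_monotone(ladder)
    return ladder


def _assert_nested_monotone(ladder: list[ModelFit]) -> None:
    # runtime invariant of nested OLS: RSS never increases with size
    for a, b in zip(ladder, ladder[1:]):
        if b.metrics.rss_tr > a.metrics.rss_tr + 1e-8 * max(1.0, a.metrics.rss_tr):
            raise AssertionError(
                "stepwise ladder violated nested-RSS monotonicity"
            )
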