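"""Internal and external validation of QSAR regression models.

Covers the standard battery a regulatory-grade QSAR is expected to pass:

* leave-one-out cross-validated Q^2 (hat-matrix shortcut),
* leave-many-out resampling Q^2,
* external-set statistics (r^2_ext and the Q^2_F1/F2/F3 family),
* Y-randomization (response scrambling) chance-correlation nulls,
* per-coefficient t statistics and variance inflation factors,
* a rule-based acceptance verdict (R^2 > 0.6, q^2 and Q^2_ext > 0.5,
  VIF in [1, 5], coefficient significance < 0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset_io import DescriptorMatrix
from .model_build import (
    FitMetrics,
    ModelFit,
    Transform,
    _design,
    _ols_core,
    apply_transform,
)

__all__ = [
    "LMOResult",
    "ExternalValidation",
    "YRandResult",
    "ValidationReport",
    "Verdict",
    "q2_loo",
    "q2_lmo",
    "external_validation",
    "y_randomization",
    "vif",
    "coefficient_tests",
    "acceptance_check",
]


def _model_design_and_y(
    model: ModelFit, X: DescriptorMatrix, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    yt = apply_transform(y, model.response_transform)
    return _design(X, model.descriptor_names), yt


def q2_loo(model: ModelFit, X: DescriptorMatrix, y: np.ndarray) -> float:
    """Leave-one-out cross-validated Q^2 = 1 - PRESS/TSS.

    PRESS is computed with the exact hat-matrix shortcut
    e_i / (1 - h_ii); a compound with h_ii = 1 has no out-of-sample
    residual and raises.
    """
    Xd, yt = _model_design_and_y(model, X, y)
    _, _, resid, _ = _ols_core(Xd, yt)
    q, _ = np.linalg.qr(Xd)
    h = np.sum(q * q, axis=1)
    if np.any(h >= 1.0 - 1e-12):
        bad = list(np.flatnonzero(h >= 1.0 - 1e-12))
        raise ZeroDivisionError(
            f"exact-leverage points (h=1) at rows {bad}; LOO undefined"
        )
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    tss = float(np.sum((yt - yt.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    return 1.0 - press / tss


@dataclass(frozen=True)
class LMOResult:
    """Leave-many-out resampling summary.

    ``per_repeat`` holds one Q^2 per resample, each computed against the
    full-training-set mean (1 - sum_held (y - yhat)^2 / sum_held
    (y - ybar_full)^2).  ``pooled`` accumulates numerator and denominator
    over all repeats before the ratio; with exhaustive leave-one-out
    draws it reduces exactly to Q^2_LOO.
    """

    mean: float
    per_repeat: np.ndarray
    pooled: float
    leave_fraction: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "pooled": self.pooled,
            "leave_fraction": self.leave_fraction,
            "per_repeat": self.per_repeat.tolist(),
        }


def q2_lmo(
    model: ModelFit,
    X: DescriptorMatrix,
    y: np.ndarray,
    leave_fraction: float = 0.3,
    repeats: int = 100,
    seed: int = 0,
    groups: Sequence[Sequence[int]] | None = None,
) -> LMOResult:
    """Leave-many-out cross-validation of a fixed descriptor subset.

    Per repeat, ceil(leave_fraction * n) compounds are held out, the
    model refit on the remainder with the same descriptors, and the
    held-out compounds predicted.  ``groups`` overrides the random draws
    with explicit hold-out index sets (used for exhaustive checks).
    """
    Xd, yt = _model_design_and_y(model, X, y)
    n, pp1 = Xd.shape
    if groups is None:
        m = int(np.ceil(leave_fraction * n))
        if not 0 < m < n:
            raise ValueError(f"infeasible leave_fraction {leave_fraction}")
        if n - m <= pp1:
            raise ValueError(
                f"leave_fraction {leave_fraction} leaves too few points to refit"
            )
        rng = np.random.default_rng(seed)
        groups = [rng.choice(n, size=m, replace=False) for _ in range(repeats)]
    ybar = yt.mean()
    per_repeat = []
    num_tot = 0.0
    den_tot = 0.0
    for idx in groups:
        idx = np.asarray(idx, dtype=int)
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        beta, _, _, _ = _ols_core(Xd[mask], yt[mask])
        pred = Xd[idx] @ beta
        num = float(np.sum((yt[idx] - pred) ** 2))
        den = float(np.sum((yt[idx] - ybar) ** 2))
        per_repeat.append(1.0 - num / den if den > 0 else 0.0)
        num_tot += num
        den_tot += den
    per_repeat = np.asarray(per_repeat)
    pooled = 1.0 - num_tot / den_tot if den_tot > 0 else 0.0
    frac = len(np.asarray(groups[0])) / n
    return LMOResult(
        mean=float(per_repeat.mean()),
        per_repeat=per_repeat,
        pooled=float(pooled),
        leave_fraction=float(frac),
    )


@dataclass(frozen=True)
class ExternalValidation:
    """External-set predictivity statistics.

    r2_ext is the squared Pearson correlation of predictions with
    observations (sign- and scale-blind); the Q^2_F* family are
    residual-based: F1 references the training mean, F2 the test mean,
    F3 the per-compound training variance.
    """

    r2_ext: float
    q2_f1: float
    q2_f2: float
    q2_f3: float

    def to_dict(self) -> dict:
        return {
            "r2_ext": self.r2_ext,
            "q2_f1": self.q2_f1,
            "q2_f2": self.q2_f2,
            "q2_f3": self.q2_f3,
        }


def external_validation(
    model: ModelFit,
    X_test: DescriptorMatrix,
    y_test: np.ndarray,
    y_train: np.ndarray,
) -> ExternalValidation:
    """Predict the held-out compounds and score the predictions.

    ``y_train`` is the raw training response (transformed internally with
    the model's transform) and supplies the reference mean/variance for
    Q^2_F1 and Q^2_F3.
    """
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    yt_test = apply_transform(y_test, model.response_transform)
    yt_train = apply_transform(y_train, model.response_transform)
    pred = model.predict(X_test)
    n_ext = len(yt_test)

    if np.ptp(pred) == 0 or np.ptp(yt_test) == 0:
        r2_ext = 0.0
    else:
        r2_ext = float(np.corrcoef(pred, yt_test)[0, 1] ** 2)
    sse = float(np.sum((yt_test - pred) ** 2))
    ss_train_mean = float(np.sum((yt_test - yt_train.mean()) ** 2))
    ss_test_mean = float(np.sum((yt_test - yt_test.mean()) ** 2))
    var_train = float(np.sum((yt_train - yt_train.mean()) ** 2)) / len(yt_train)
    q2_f1 = 1.0 - sse / ss_train_mean if ss_train_mean > 0 else 0.0
    q2_f2 = 1.0 - sse / ss_test_mean if ss_test_mean > 0 else 0.0
    q2_f3 = 1.0 - (sse / n_ext) / var_train if var_train > 0 else 0.0
    return ExternalValidation(r2_ext, q2_f1, q2_f2, q2_f3)


@dataclass(frozen=True)
class YRandResult:
    """Chance-correlation null from response scrambling."""

    r2: np.ndarray
    q2: np.ndarray

    @property
    def max_r2(self) -> float:
        return float(self.r2.max())

    @property
    def mean_r2(self) -> float:
        return float(self.r2.mean())

    @property
    def max_q2(self) -> float:
        return float(self.q2.max())

    @property
    def mean_q2(self) -> float:
        return float(self.q2.mean())

    def to_dict(self) -> dict:
        return {
            "max_r2": self.max_r2,
            "mean_r2": self.mean_r2,
            "max_q2": self.max_q2,
            "mean_q2": self.mean_q2,
            "r2": self.r2.tolist(),
            "q2": self.q2.tolist(),
        }


def y_randomization(
    X: DescriptorMatrix,
    y: np.ndarray,
    subset: Sequence[str],
    transform: Transform = "identity",
    n_perm: int = 300,
    seed: int = 0,
    permutations: Sequence[np.ndarray] | None = None,
) -> YRandResult:
    """Scramble the response, refit the fixed subset, record (R^2, Q^2).

    A real structure-activity relationship cannot survive scrambling:
    the null distribution of R^2_yrand/Q^2_yrand should sit far below
    the original model's values.  ``permutations`` lets a caller force
    explicit index arrays (e.g. the identity) for verification.
    """
    if n_perm < 1 and permutations is None:
        raise ValueError("n_perm must be >= 1")
    yt = apply_transform(y, transform)
    Xd = _design(X, subset)
    n = len(yt)
    tss = float(np.sum((yt - yt.mean()) ** 2))
    q, _ = np.linalg.qr(Xd)
    h = np.sum(q * q, axis=1)
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(n) for _ in range(n_perm)]
    r2s, q2s = [], []
    for perm in permutations:
        yp = yt[np.asarray(perm, dtype=int)]
        _, _, resid, rss = _ols_core(Xd, yp)
        r2s.append(1.0 - rss / tss if tss > 0 else 0.0)
        press = float(np.sum((resid / (1.0 - h)) ** 2))
        q2s.append(1.0 - press / tss if tss > 0 else 0.0)
    return YRandResult(np.asarray(r2s), np.asarray(q2s))


def vif(X: DescriptorMatrix, subset: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors VIF_j = 1/(1 - R^2_j).

    R^2_j comes from regressing descriptor j on the other subset columns
    (with intercept).  Perfect collinearity yields +inf rather than an
    exception so diagnostics can still be reported.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("VIF needs at least 2 descriptors")
    cols = X.columns(subset)
    if np.any(np.ptp(cols, axis=0) == 0):
        bad = [s for s, c in zip(subset, cols.T) if np.ptp(c) == 0]
        raise ValueError(f"constant descriptor columns: {bad}")
    out: dict[str, float] = {}
    for j, name in enumerate(subset):
        yj = cols[:, j]
        others = np.delete(cols, j, axis=1)
        Xd = np.column_stack([np.ones(len(yj)), others])
        beta, _, _, _ = np.linalg.lstsq(Xd, yj, rcond=None)
        resid = yj - Xd @ beta
        rss = float(resid @ resid)
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2j = 1.0 - rss / tss if tss > 0 else 0.0
        out[name] = float("inf") if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return out


def coefficient_tests(model: ModelFit) -> dict[str, tuple[float, float]]:
    """Per-descriptor t statistic and two-sided p-value.

    t = coefficient / OLS standard error, referred to Student t with
    n - p - 1 degrees of freedom.
    """
    df = model.n_train - model.p - 1
    out: dict[str, tuple[float, float]] = {}
    for name in model.descriptor_names:
        se = model.std_errors[name]
        t = model.coefficients[name] / se if se > 0 else float("inf")
        sig = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        out[name] = (float(t), sig)
    return out


@dataclass
class ValidationReport:
    """Aggregate internal/external validation results for one model."""

    q2_loo: float
    q2_lmo: LMOResult | None = None
    external: ExternalValidation | None = None
    yrand: YRandResult | None = None
    vif: dict[str, float] = field(default_factory=dict)
    coef_tests: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "q2_loo": self.q2_loo,
            "q2_lmo": self.q2_lmo.to_dict() if self.q2_lmo else None,
            "external": self.external.to_dict() if self.external else None,
            "yrand": self.yrand.to_dict() if self.yrand else None,
            "vif": dict(self.vif),
            "coef_tests": {
                k: {"t": v[0], "sig": v[1]} for k, v in self.coef_tests.items()
            },
        }


@dataclass(frozen=True)
class Verdict:
    passed: bool
    reasons: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"passed": self.passed, "reasons": list(self.reasons)}


def acceptance_check(
    fit: FitMetrics,
    val: ValidationReport,
    r2_min: float = 0.6,
    q2_min: float = 0.5,
    q2_ext_min: float = 0.5,
    vif_range: tuple[float, float] = (1.0, 5.0),
    sig_max: float = 0.05,
) -> Verdict:
    """Rule-based model acceptance.

    Pass requires R^2 above 0.6, internal q^2 (LOO) and external Q^2
    above 0.5, every VIF inside [1, 5], and every coefficient
    significant at 0.05.  Each violated rule is named in the verdict.
    """
    reasons: list[str] = []
    if not fit.r_squared > r2_min:
        reasons.append(f"R² ≤ {r2_min} (got {fit.r_squared:.3f})")
    if not val.q2_loo > q2_min:
        reasons.append(f"q² ≤ {q2_min} (got {val.q2_loo:.3f})")
    if val.external is not None and not val.external.q2_f1 > q2_ext_min:
        reasons.append(f"Q²_ext ≤ {q2_ext_min} (got {val.external.q2_f1:.3f})")
    lo, hi = vif_range
    for name, v in val.vif.items():
        if not lo <= v <= hi:
            reasons.append(f"VIF outside {lo}–{hi}: {name} = {v:.3f}")
    for name, (_, sig) in val.coef_tests.items():
        if not sig < sig_max:
            reasons.append(f"sig ≥ {sig_max}: {name} = {sig:.3f}")
    return Verdict(passed=not reasons, reasons=tuple(reasons))
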