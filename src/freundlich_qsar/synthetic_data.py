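"""Synthetic descriptor matrices, responses and isotherm curves.

Every downstream stage of the QSAR workflow (stepwise model building,
cross-validation, applicability-domain analysis) is exercised against
data with known ground truth generated here.  Descriptor columns emulate
the value ranges of the real quantum-chemical parameters (atomic-charge
sums in e, orbital energies in eV, Wiberg/bond indices dimensionless);
the joint distribution is a latent equicorrelated Gaussian copula mapped
affinely into each column's range — ranges and correlation are emulated,
not the true joint law of DFT descriptors.

Seeding: one integer seed drives all streams.  Each operation draws from
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed k per
stream (0 = descriptors, 1 = response noise, 2 = isotherm noise), so the
same seed reproduces every artifact bit-exactly and the streams are
mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import DescriptorMatrix
from .isotherm import IsothermData

__all__ = [
    "SyntheticSpec",
    "DEFAULT_DESCRIPTOR_RANGES",
    "generate_descriptor_matrix",
    "generate_linear_response",
    "generate_isotherm_data",
]


# Default per-descriptor (low, high) bounds for the 31 emulated
# quantum-chemical parameters.  Where the study prints observed extrema
# (charge descriptors, Wiberg and C-C bond indices, E_LUMO, Fukui(-)_max,
# total energy) those are used verbatim; the remaining bounds are
# physically plausible values on each descriptor's natural scale.
DEFAULT_DESCRIPTOR_RANGES: dict[str, tuple[float, float]] = {
    "dipole_moment": (0.0, 8.0),
    "E_total": (-7761.158, -232.333),
    "E_HOMO": (-0.35, -0.15),
    "E_LUMO": (-0.145, 0.040),
    "E_gap": (0.05, 0.35),
    "q(CH+)_max": (0.039, 0.198),
    "q(CH+)_min": (0.020, 0.129),
    "q(C-)_max": (-0.045, 0.219),
    "q(C-)_min": (-0.137, 0.034),
    "sum_q(H)": (0.0, 1.2),
    "sum_q(O)": (-1.6, 0.0),
    "sum_q(N)": (-0.9, 0.2),
    "sum_q(O+N)": (-1.554, 0.154),
    "sum_q(-)": (-2.0, 0.0),
    "sum_q(-)/N_C": (-0.061, 0.060),
    "Wiberg(C-C)_max": (3.893, 4.083),
    "Wiberg(C-C)_min": (1.072, 3.963),
    "Wiberg(C-H)_max": (0.88, 0.96),
    "Wiberg(C-H)_min": (0.82, 0.94),
    "Bond_orders(C-C)_min": (-1.610, -0.658),
    "Bond_orders(C-C)_max": (-1.1, -0.3),
    "Bond_orders(C-H)_min": (-1.0, -0.5),
    "Fukui(-)_max": (0.087, 0.471),
    "Fukui(-)_min": (0.0, 0.15),
    "Fukui(+)_max": (0.05, 0.45),
    "Fukui(+)_min": (0.0, 0.12),
    "Fukui(0)_max": (0.05, 0.40),
    "Fukui(0)_min": (0.0, 0.13),
    "hardness": (0.02, 0.18),
    "electronegativity": (0.08, 0.25),
    "electrophilicity": (0.02, 0.35),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic data-generating process.

    ``beta`` is sparse: descriptors absent from the map have zero
    coefficient.  ``correlation`` is the common pairwise correlation of
    the latent Gaussian before the per-column range mapping.
    """

    n_compounds: int = 47
    descriptor_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_RANGES)
    )
    correlation: float = 0.3
    beta: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, (lo, hi) in self.descriptor_ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {name!r} must have low < high")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_descriptor_matrix(spec: SyntheticSpec) -> DescriptorMatrix:
    """Draw an n_compounds x p descriptor matrix.

    Latent construction: Z_ij = sqrt(rho) * g_i + sqrt(1-rho) * e_ij with
    g, e standard normal, giving equicorrelation rho across columns; the
    Gaussian CDF maps Z into (0,1) and an affine map into each column's
    [low, high].  Columns therefore never leave their configured bounds.
    """
    if spec.n_compounds < 2:
        raise ValueError("need at least 2 compounds")
    names = list(spec.descriptor_ranges)
    p = len(names)
    rng = _rng(spec.seed, 0)
    g = rng.standard_normal((spec.n_compounds, 1))
    e = rng.standard_normal((spec.n_compounds, p))
    z = np.sqrt(spec.correlation) * g + np.sqrt(1.0 - spec.correlation) * e
    u = stats.norm.cdf(z)
    lows = np.array([spec.descriptor_ranges[n][0] for n in names])
    highs = np.array([spec.descriptor_ranges[n][1] for n in names])
    x = lows + u * (highs - lows)
    compounds = [f"synthetic-{i + 1:03d}" for i in range(spec.n_compounds)]
    df = pd.DataFrame(x, index=pd.Index(compounds, name="name"), columns=names)
    return DescriptorMatrix(df)


def generate_linear_response(
    X: DescriptorMatrix, spec: SyntheticSpec
) -> np.ndarray:
    """y = intercept + sum_j beta_j x_j + eps, eps ~ N(0, noise_sd^2)."""
    missing = [k for k in spec.beta if k not in X.descriptor_names]
    if missing:
        raise KeyError(f"beta names not in descriptor matrix: {missing}")
    y = np.full(X.shape[0], float(spec.intercept))
    for name, b in spec.beta.items():
        y = y + b * X.df[name].to_numpy(dtype=float)
    if spec.noise_sd > 0:
        rng = _rng(spec.seed, 1)
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    return y


def generate_isotherm_data(
    K: float,
    one_over_n: float,
    Ce_grid: np.ndarray,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> IsothermData:
    """Noisy batch-equilibrium points from Qe = K * Ce^(1/n).

    Noise is multiplicative, Qe = K*Ce^(1/n) * (1 + eta) with
    eta ~ N(0, noise_cv^2) redrawn until 1 + eta > 0 (adsorbed amounts
    scale with magnitude and must stay positive).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    ce = np.asarray(Ce_grid, dtype=float)
    if np.any(ce <= 0):
        raise ValueError("all Ce must be strictly positive")
    qe = K * ce ** one_over_n
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if noise_cv > 0:
        rng = _rng(seed, 2)
        eta = rng.normal(0.0, noise_cv, size=len(ce))
        for _ in range(1000):
            bad = eta <= -1.0
            if not bad.any():
                break
            eta[bad] = rng.normal(0.0, noise_cv, size=int(bad.sum()))
        qe = qe * (1.0 + eta)
    return IsothermData(Ce=ce, Qe=qe)
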