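"""Chemical-space coverage via fingerprint Tanimoto similarity and MDS.

Binary molecular fingerprints are consumed as bitstring tables (the
fingerprint family and length are caller's choice); pairwise Tanimoto
similarity T = c / (|a| + |b| - c) is converted to the distance 1 - T
and embedded in 2-D by classical (Torgerson) multidimensional scaling so
training- and test-set coverage can be inspected on one map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FingerprintSet",
    "Embedding2D",
    "tanimoto_matrix",
    "classical_mds",
]


@dataclass(frozen=True)
class FingerprintSet:
    """Named fixed-length binary fingerprints."""

    compound_names: tuple[str, ...]
    bits: np.ndarray  # (n_compounds, n_bits) boolean

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        if bits.ndim != 2 or bits.shape[1] < 1:
            raise ValueError("bits must be a 2-D array with >= 1 column")
        if bits.shape[0] != len(self.compound_names):
            raise ValueError("one fingerprint row per compound name required")
        object.__setattr__(self, "bits", bits)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FingerprintSet":
        """CSV dialect: first column = name; either one 0/1 column per bit,
        or a single ``hex`` column of packed hexadecimal strings."""
        df = pd.read_csv(path, dtype=str)
        names = tuple(df.iloc[:, 0])
        rest = df.iloc[:, 1:]
        if list(rest.columns) == ["hex"]:
            strs = [s.strip() for s in rest["hex"]]
            width = max(len(s) for s in strs) * 4
            rows = [
                [b == "1" for b in bin(int(s, 16))[2:].zfill(width)]
                for s in strs
            ]
            return cls(names, np.asarray(rows))
        return cls(names, rest.to_numpy(dtype=float) > 0.5)


@dataclass(frozen=True)
class Embedding2D:
    """Low-dimensional MDS coordinates with the eigenvalue spectrum kept
    for diagnostics (negative eigenvalues flag non-Euclidean input)."""

    compound_names: tuple[str, ...]
    coords: np.ndarray  # (n, dims), column means 0
    eigenvalues: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim{j + 1}": self.coords[:, j] for j in range(self.coords.shape[1])}
        return pd.DataFrame({"name": self.compound_names, **cols})


def tanimoto_matrix(fps: FingerprintSet) -> np.ndarray:
    """Pairwise Tanimoto similarity T(a,b) = c / (|a| + |b| - c).

    Diagonal is 1; a pair of all-zero fingerprints is defined as
    similarity 1 (identical absence of features) — such compounds are
    indistinguishable to the fingerprint.
    """
    b = fps.bits.astype(np.int64)
    n = b.shape[0]
    if n < 2:
        raise ValueError("need at least 2 compounds")
    c = b @ b.T  # shared on-bits
    pop = b.sum(axis=1)
    denom = pop[:, None] + pop[None, :] - c
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, c / np.maximum(denom, 1), 1.0)
    np.fill_diagonal(t, 1.0)
    return t


def classical_mds(
    similarity: np.ndarray, dims: int = 2, names: Sequence[str] | None = None
) -> Embedding2D:
    """Classical (Torgerson) MDS of the distance D = 1 - T.

    Double-centers -D^2/2, takes the top ``dims`` eigenpairs (descending
    eigenvalue, index order on ties) and scales eigenvectors by
    sqrt(max(eigenvalue, 0)).  Axis signs are fixed by making the first
    nonzero coordinate of each axis positive, so embeddings are fully
    deterministic.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("similarity must be symmetric")
    n = s.shape[0]
    d = 1.0 - s
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2  # clean numerical asymmetry
    evals, evecs = np.linalg.eigh(b)  # ascending
    order = np.argsort(-evals, kind="stable")[:dims]
    lam = evals[order]
    vec = evecs[:, order]
    coords = vec * np.sqrt(np.maximum(lam, 0.0))
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, k] = -col
    coords = coords - coords.mean(axis=0)
    if names is None:
        names = tuple(f"compound-{i + 1}" for i in range(n))
    return Embedding2D(tuple(names), coords, evals[np.argsort(-evals, kind="stable")])
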