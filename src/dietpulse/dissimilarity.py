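"""Bray-Curtis dissimilarity and principal coordinates analysis (PCoA).

Bray-Curtis is the workhorse dissimilarity for sparse community matrices
(it ignores joint absences), and PCoA is the geometric substrate shared by
the dispersion (diet breadth) test and NMDS initialization.  Bray-Curtis
matrices are generally non-Euclidean, so PCoA keeps the negative-eigenvalue
axes explicitly as an "imaginary" branch: squared distances decompose as
(real part) - (imaginary part), which is exactly what the distance-to-
centroid computation downstream needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_data import CommunityMatrix, ValidationError

__all__ = ["DissimilarityMatrix", "PcoaResult", "bray_curtis", "pcoa"]

#: Relative eigenvalue cutoff: |lambda| <= RTOL * max|lambda| is noise.
EIG_RTOL = 1e-8


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with per-unit grouping labels."""

    d: np.ndarray
    unit_labels: pd.DataFrame
    metric_name: str = "braycurtis"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValidationError("dissimilarity matrix must be square")
        if len(self.unit_labels) != n:
            raise ValidationError("unit_labels length does not match matrix size")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("dissimilarity matrix must have a zero diagonal")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n_units(self) -> int:
        return self.d.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_csv(self, path: str | Path) -> None:
        ids = self.unit_labels["specimen_id"].tolist()
        pd.DataFrame(self.d, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(
        cls, path: str | Path, metric_name: str = "braycurtis"
    ) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = pd.DataFrame({"specimen_id": df.index.astype(str)})
        return cls(df.values, labels, metric_name)


@dataclass
class PcoaResult:
    """Principal coordinates split into real and imaginary branches.

    ``real_coords`` columns correspond to positive eigenvalues (descending);
    ``imag_coords`` columns to negative eigenvalues (descending by absolute
    value).  With all axes retained, for units j,k:

        d[j,k]^2 = ||xr_j - xr_k||^2 - ||xi_j - xi_k||^2.
    """

    real_coords: np.ndarray
    imag_coords: np.ndarray
    eigenvalues: np.ndarray  # positive branch then negative branch

    @property
    def n_units(self) -> int:
        return self.real_coords.shape[0]


def bray_curtis(matrix: CommunityMatrix) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities between the matrix rows.

    d_jk = sum_i |y_ij - y_ik| / sum_i (y_ij + y_ik); bounded in [0, 1] for
    nonnegative data, 1 exactly for disjoint supports.  All-zero rows are a
    constructor-level error upstream (empty stomachs never reach here).
    """
    X = matrix.values
    if np.any(X.sum(axis=1) == 0):
        bad = matrix.unit_labels.loc[X.sum(axis=1) == 0, "specimen_id"].tolist()
        raise ValidationError(f"all-zero rows (units {bad}) have undefined distances")
    d = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(d, matrix.unit_labels.copy(), "braycurtis")


def pcoa(D: DissimilarityMatrix) -> PcoaResult:
    """Gower-centered eigendecomposition of a dissimilarity matrix.

    Centers A = -d^2/2 by G = (I - 11'/n) A (I - 11'/n), eigendecomposes G,
    scales eigenvectors by sqrt(|lambda|), and drops axes with
    |lambda| <= 1e-8 * max|lambda|.  Negative eigenvalues (non-Euclidean
    structure) form the imaginary branch rather than being discarded or
    corrected away, so downstream squared distances can subtract them.
    """
    d = D.d
    n = d.shape[0]
    if n == 1:
        return PcoaResult(
            real_coords=np.zeros((1, 0)),
            imag_coords=np.zeros((1, 0)),
            eigenvalues=np.zeros(0),
        )
    A = -0.5 * d**2
    G = A - A.mean(axis=0) - A.mean(axis=1)[:, None] + A.mean()
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    tol = EIG_RTOL * np.max(np.abs(eigval)) if eigval.size else 0.0
    pos = np.where(eigval > tol)[0][::-1]  # descending
    neg = np.where(eigval < -tol)[0]  # ascending -> most negative first
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return PcoaResult(
        real_coords=real,
        imag_coords=imag,
        eigenvalues=np.concatenate([eigval[pos], eigval[neg]]),
    )
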