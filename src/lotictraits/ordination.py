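"""Dissimilarity and ordination of community compositions.

Community tables (samples x taxa, or samples x trait modalities) are compared
with the Bray-Curtis dissimilarity, d(x, y) = sum|x_i - y_i| / sum(x_i + y_i),
and embedded with principal coordinates analysis (classical metric scaling).
Because Bray-Curtis is only a semi-metric, the doubly centered matrix can have
negative eigenvalues; the corresponding "imaginary" axes are retained here
rather than corrected away, because the multivariate-dispersion analysis
subtracts their contribution when measuring distances to group centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = ["log_transform", "bray_curtis", "pcoa", "OrdinationResult"]


def log_transform(abundances: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Apply the ln(x + 1) transform to a nonnegative abundance table.

    Natural logarithm; zeros map to zero, so absence is preserved. Raises
    ``ValueError`` on negative entries.
    """
    values = np.asarray(abundances, dtype=float)
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValueError(f"negative abundance at position {tuple(bad)}")
    out = np.log1p(values)
    if isinstance(abundances, pd.DataFrame):
        return pd.DataFrame(out, index=abundances.index, columns=abundances.columns)
    return out


def bray_curtis(data: pd.DataFrame | np.ndarray, ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix between the rows of ``data``.

    Parameters
    ----------
    data
        Samples x variables matrix of nonnegative values (counts, transformed
        abundances, or community trait profiles).
    ids
        Sample identifiers; taken from the DataFrame index when omitted.

    Returns
    -------
    skbio.DistanceMatrix
        Symmetric, hollow, entries in [0, 1].
    """
    if isinstance(data, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in data.index]
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(values.shape[0])]
    if np.any(values < 0):
        raise ValueError("Bray-Curtis requires nonnegative data")
    row_sums = values.sum(axis=1)
    if np.any(row_sums == 0):
        empty = [ids[i] for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"all-zero sample(s): {empty}")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(ids))


@dataclass
class OrdinationResult:
    """Principal coordinates of a distance matrix.

    Attributes
    ----------
    eigenvalues
        All eigenvalues of the doubly centered matrix, descending.
    coordinates
        Samples x real axes (eigenvalues > tol), scaled by sqrt(eigenvalue).
    imaginary_coordinates
        Samples x imaginary axes (eigenvalues < -tol), scaled by
        sqrt(-eigenvalue); squared distances along these axes *subtract*.
    n_negative
        Number of eigenvalues below -tol.
    """

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    imaginary_coordinates: pd.DataFrame
    n_negative: int
    sample_ids: list[str] = field(default_factory=list)

    @property
    def proportion_explained(self) -> np.ndarray:
        positive = self.eigenvalues[self.eigenvalues > 0]
        return positive / positive.sum()


# relative tolerance classifying eigenvalues as zero (floating-point rank deficiency)
_EIG_RTOL = 1e-10


def pcoa(dm: DistanceMatrix | np.ndarray, ids=None) -> OrdinationResult:
    """Classical scaling (principal coordinates analysis) of a distance matrix.

    The squared distances are Gower-centered (G = -1/2 J D^2 J with J the
    centering projector) and eigendecomposed. Axes with positive eigenvalues
    carry real coordinates sqrt(lambda_k) v_k; axes with negative eigenvalues
    (semi-metric input) are kept as imaginary coordinates sqrt(-lambda_k) v_k.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.data
        ids = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if ids is None:
            ids = [str(i) for i in range(d.shape[0])]
        ids = list(ids)

    n = d.shape[0]
    a = -0.5 * d**2
    row_means = a.mean(axis=1, keepdims=True)
    col_means = a.mean(axis=0, keepdims=True)
    g = a - row_means - col_means + a.mean()

    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = _EIG_RTOL * max(np.abs(eigvals).max(), 1e-300)
    pos = eigvals > tol
    neg = eigvals < -tol

    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])

    coordinates = pd.DataFrame(
        real, index=ids, columns=[f"PCo{k + 1}" for k in range(real.shape[1])]
    )
    imaginary = pd.DataFrame(
        imag, index=ids, columns=[f"iPCo{k + 1}" for k in range(imag.shape[1])]
    )
    return OrdinationResult(
        eigenvalues=eigvals,
        coordinates=coordinates,
        imaginary_coordinates=imaginary,
        n_negative=int(neg.sum()),
        sample_ids=ids,
    )
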