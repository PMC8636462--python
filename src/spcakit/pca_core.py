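"""Ordinary PCA and the shared linear-algebra primitives.

Principal component analysis of a centered and scaled data matrix ``X``
(``I`` observations by ``J`` variables) admits three classical, equivalent
formulations:

``ls-orthP``
    Least-squares low-rank approximation ``min ||X - T P'||_F^2`` subject to
    ``P'P = I``; solved by the truncated SVD ``X = U D V'`` with ``T = U D``,
    ``P = V``.
``ls-orthT``
    The psychometric variant with orthogonality on the scores,
    ``T'T = (I-1) I``; solved by ``T = (I-1)^{1/2} U``,
    ``P = (I-1)^{-1/2} V D`` and weights ``W = (I-1)^{1/2} V D^{-1}``.
``maxvar``
    Maximal component variance with orthonormal weights; solved by the
    eigenvectors of the covariance matrix, ``W = V``, ``T = X W``.

All three give the same reconstruction ``T P'``.  Every sparse method in this
package breaks that equivalence, which is why the shared primitives live
here: a deterministic truncated SVD, the soft-thresholding operator, the
orthogonal Procrustes/polar factor, and rank-one deflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "DataMatrix",
    "ComponentModel",
    "SVDTriple",
    "center_scale",
    "truncated_svd",
    "pca_fit",
    "soft_threshold",
    "procrustes_rotation",
    "deflate",
    "as_matrix",
]


@dataclass
class DataMatrix:
    """A numeric observations-by-variables matrix with optional identifiers.

    Attributes
    ----------
    values : ndarray of shape (I, J)
        The data.  When ``standardized`` is True each column has mean 0 and
        sample standard deviation 1 (denominator ``I - 1``).
    row_ids, col_ids : list of str or None
        Observation and variable identifiers.
    standardized : bool
        Whether :func:`center_scale` has been applied.
    column_means, column_sds : ndarray or None
        The statistics removed by standardization; the raw data are
        ``values * column_sds + column_means``.
    """

    values: np.ndarray
    row_ids: list | None = None
    col_ids: list | None = None
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_var(self) -> int:
        return self.values.shape[1]


@dataclass
class ComponentModel:
    """A fitted component solution (scores T, loadings P, weights W).

    ``weights`` is None for methods that only estimate loadings (rotation +
    thresholding, sparse rank-one SVD).  Whenever weights are present the
    stored scores equal ``X @ weights``.
    """

    scores: np.ndarray
    loadings: np.ndarray
    weights: np.ndarray | None
    n_components: int
    method: str
    formulation: str | None = None
    extras: dict = field(default_factory=dict)

    def reconstruction(self) -> np.ndarray:
        return self.scores @ self.loadings.T


@dataclass
class SVDTriple:
    """Truncated SVD ``X ~= U @ diag(D) @ V.T`` with a fixed sign convention."""

    U: np.ndarray
    D: np.ndarray
    V: np.ndarray


def as_matrix(X) -> np.ndarray:
    """Return the underlying ndarray of a DataMatrix or array-like."""
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=float)


def center_scale(raw, row_ids=None, col_ids=None) -> DataMatrix:
    """Center each column and scale it to unit sample variance (ddof=1).

    Raises
    ------
    ValueError
        If the input has missing values, fewer than two rows, or a constant
        column (named in the message).
    """
    values = np.asarray(getattr(raw, "values", raw), dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D observations-by-variables matrix")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 observations to standardize")
    if not np.isfinite(values).all():
        raise ValueError("input matrix contains missing or non-finite values")
    if col_ids is None and hasattr(raw, "columns"):
        col_ids = list(raw.columns)
    if row_ids is None and hasattr(raw, "index"):
        row_ids = list(raw.index)

    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    bad = np.nonzero(sds <= 0)[0]
    if bad.size:
        names = [str(col_ids[j]) if col_ids is not None else str(j) for j in bad]
        raise ValueError(f"constant column(s) cannot be scaled: {', '.join(names)}")
    standardized = (values - means) / sds
    return DataMatrix(
        values=standardized,
        row_ids=list(row_ids) if row_ids is not None else None,
        col_ids=list(col_ids) if col_ids is not None else None,
        standardized=True,
        column_means=means,
        column_sds=sds,
    )


def _apply_sign_convention(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Flip each column of V so its largest-magnitude entry is positive
    # (ties broken by the first index); flip U accordingly so U D V' is
    # unchanged.  Makes the decomposition deterministic across runs.
    U = U.copy()
    V = V.copy()
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return U, V


def truncated_svd(X, K: int) -> SVDTriple:
    """Rank-``K`` truncated SVD with deterministic column signs.

    The discarded tail satisfies the Eckart-Young identity: the squared
    Frobenius reconstruction error equals the sum of squared discarded
    singular values.
    """
    values = as_matrix(X)
    I, J = values.shape
    if not 1 <= K <= min(I, J):
        raise ValueError(f"K={K} out of range [1, {min(I, J)}]")
    U, s, Vt = scipy.linalg.svd(values, full_matrices=False)
    U, V = _apply_sign_convention(U[:, :K], Vt[:K].T)
    return SVDTriple(U=U, D=s[:K].copy(), V=V)


def pca_fit(X, K: int, formulation: str = "ls-orthP") -> ComponentModel:
    """Ordinary PCA under one of the three equivalent formulations.

    Parameters
    ----------
    X : DataMatrix or ndarray
        Standardized data (unstandardized input is accepted for unit-scale
        experiments; the factorization is applied as-is).
    K : int
        Number of components.
    formulation : {"ls-orthP", "ls-orthT", "maxvar"}
        Which constraint set to honor; the reconstruction ``T P'`` is
        identical for all three.
    """
    values = as_matrix(X)
    I = values.shape[0]
    svd = truncated_svd(values, K)
    U, D, V = svd.U, svd.D, svd.V
    if formulation == "ls-orthP":
        T = U * D
        P = V
        W = V  # X V = U D = T
    elif formulation == "ls-orthT":
        if np.any(D <= np.finfo(float).eps * max(values.shape) * (D[0] if D.size else 1.0)):
            raise ValueError(
                "ls-orthT requires K nonzero singular values (D^-1 undefined)"
            )
        s = np.sqrt(I - 1)
        T = s * U
        P = (V * D) / s
        W = s * (V / D)
    elif formulation == "maxvar":
        W = V
        T = values @ W
        P = V
    else:
        raise ValueError(f"unknown formulation: {formulation!r}")
    return ComponentModel(
        scores=T,
        loadings=P,
        weights=W,
        n_components=K,
        method="pca",
        formulation=formulation,
        extras={"singular_values": D},
    )


def soft_threshold(x, lam: float) -> np.ndarray:
    """Soft-thresholding operator ``S(x, lam) = sign(x) * max(|x| - lam, 0)``."""
    if lam < 0:
        raise ValueError("soft-threshold parameter must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def procrustes_rotation(M) -> np.ndarray:
    """Orthogonal polar factor ``Q = A B'`` of the thin SVD ``M = A S B'``.

    ``Q`` maximizes ``Tr(Q' M)`` over (semi-)orthogonal matrices of the same
    shape; for a square ``M`` it is the closest orthogonal matrix.  This is
    the closed-form solution of the orthogonal Procrustes problem used by
    the elastic-net sparse PCA loading update.
    """
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValueError("non-finite input")
    A, _, Bt = scipy.linalg.svd(M, full_matrices=False)
    return A @ Bt


def deflate(X, t, p):
    """Remove a rank-one term: ``X - t p'``.

    Returns an ndarray (or a DataMatrix-wrapped ndarray when given one).
    """
    values = as_matrix(X)
    t = np.asarray(t, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if t.shape[0] != values.shape[0] or p.shape[0] != values.shape[1]:
        raise ValueError(
            f"dimension mismatch: X is {values.shape}, t has length {t.shape[0]}, "
            f"p has length {p.shape[0]}"
        )
    residual = values - np.outer(t, p)
    if isinstance(X, DataMatrix):
        return DataMatrix(values=residual, row_ids=X.row_ids, col_ids=X.col_ids)
    return residual


def least_squares_loadings(X, T: np.ndarray) -> np.ndarray:
    """Loadings ``P = X' T (T'T)^{-1}`` that best reconstruct X from scores T.

    Used to make the percentage of explained variance well-defined for
    weight-based sparse methods, whose native output is W rather than P.
    """
    values = as_matrix(X)
    G = T.T @ T
    return values.T @ (T @ scipy.linalg.inv(G))


def warn_nonconvergence(name: str, iterations: int) -> None:
    warnings.warn(
        f"{name} did not converge within {iterations} iterations; "
        "returning the last iterate",
        RuntimeWarning,
        stacklevel=3,
    )
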