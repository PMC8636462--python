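"""Performance measures for comparing estimated and true component structure.

All measures except the percentage of explained variance are sensitive to
the column order and sign of a component solution, which the estimators only
determine up to permutation and reflection.  :func:`align_components`
therefore searches all ``2^K * K!`` sign/permutation combinations and the
chosen alignment is applied consistently to scores, loadings and weights.

Measures
--------
- squared relative error, ``SRE(A) = ||A_hat - A||_F^2 / ||A||_F^2``
- misidentification rate, MR: fraction of true zeros not estimated as zero
- percentage of explained variance, ``PEV = 1 - ||T P' - X||_F^2 / ||X||_F^2``
- Tucker congruence / cosine similarity: mean columnwise cosine
- index of sparseness, ``IS = PEV_sparse * PEV_pca * PS`` (maximized to tune
  the sparsity level on empirical data)
- ``R^2_inf(omega, c) = (omega^2 - c)_+ / (omega^2 + c*omega)``, the
  almost-sure limit of the squared cosine between the estimated and true
  leading eigenvector when J/I -> c: a diagnostic for the inconsistency of
  ordinary PCA in high dimensions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .pca_core import as_matrix

__all__ = [
    "MetricsRecord",
    "sre",
    "mr",
    "pev",
    "cossim",
    "align_components",
    "apply_alignment",
    "index_of_sparseness",
    "r_inf_squared",
]


@dataclass
class MetricsRecord:
    """Metric values for one (dataset, method) pair after alignment."""

    method: str
    sre_scores: float | None = None
    sre_loadings: float | None = None
    sre_weights: float | None = None
    mr: float = math.nan
    pev: float = math.nan
    cossim_scores: float | None = None
    cossim_crossparam: float | None = None
    is_value: float | None = None
    alignment: tuple | None = None
    failed: bool = False

    def as_dict(self) -> dict:
        out = {}
        for name in (
            "sre_scores",
            "sre_loadings",
            "sre_weights",
            "mr",
            "pev",
            "cossim_scores",
            "cossim_crossparam",
            "is_value",
        ):
            value = getattr(self, name)
            if value is not None:
                out[name] = float(value)
        return out


def sre(A_hat, A) -> float:
    """Squared relative error ``||A_hat - A||_F^2 / ||A||_F^2``."""
    A_hat = np.asarray(A_hat, dtype=float)
    A = np.asarray(A, dtype=float)
    if A_hat.shape != A.shape:
        raise ValueError(f"shape mismatch: {A_hat.shape} vs {A.shape}")
    denom = float(np.sum(A**2))
    if denom == 0:
        raise ValueError("reference matrix is all zero; SRE undefined")
    return float(np.sum((A_hat - A) ** 2) / denom)


def mr(zero_mask_true, zero_mask_est) -> float:
    """Misidentification rate: fraction of true zeros not estimated as zero.

    Returns NaN ("missing") when the truth has no zeros at all, mirroring
    the convention of not reporting MR in zero-sparsity conditions.
    """
    true = np.asarray(zero_mask_true, dtype=bool)
    est = np.asarray(zero_mask_est, dtype=bool)
    if true.shape != est.shape:
        raise ValueError(f"shape mismatch: {true.shape} vs {est.shape}")
    n_true = int(true.sum())
    if n_true == 0:
        return math.nan
    missed = int(np.sum(true & ~est))
    return missed / n_true


def pev(X, T_hat, P_hat) -> float:
    """Percentage of explained variance of the reconstruction ``T_hat P_hat'``."""
    values = as_matrix(X)
    X_hat = np.asarray(T_hat, dtype=float) @ np.asarray(P_hat, dtype=float).T
    total = float(np.sum(values**2))
    value = 1.0 - float(np.sum((X_hat - values) ** 2)) / total
    if value < 0:
        warnings.warn(
            "reconstruction error exceeds the data norm; PEV clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return min(value, 1.0)


def cossim(A, B) -> float:
    """Mean columnwise cosine (Tucker congruence) between two matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("matrices must have the same number of columns")
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero column; cosine undefined")
    return float(np.mean(np.sum(A * B, axis=0) / (na * nb)))


def align_components(A_hat, A, objective: str = "min-sre") -> tuple[tuple, np.ndarray]:
    """Best column permutation and signs matching ``A_hat`` to ``A``.

    Exhaustive search over all ``K! * 2^K`` combinations (K <= 6), choosing
    the one minimizing SRE or maximizing the mean columnwise cosine.

    Returns
    -------
    (permutation, signs)
        ``A_hat[:, permutation] * signs`` is the aligned estimate.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    A = np.asarray(A, dtype=float)
    K = A.shape[1]
    if K > 6:
        raise ValueError(
            "exhaustive alignment is limited to K <= 6 components; a "
            "Hungarian-assignment approximation is not implemented"
        )
    if objective not in ("min-sre", "max-cossim"):
        raise ValueError("objective must be 'min-sre' or 'max-cossim'")
    best = None
    best_val = None
    for perm in itertools.permutations(range(K)):
        permuted = A_hat[:, perm]
        for signs in itertools.product((1.0, -1.0), repeat=K):
            candidate = permuted * np.asarray(signs)
            if objective == "min-sre":
                val = float(np.sum((candidate - A) ** 2))
                better = best_val is None or val < best_val
            else:
                val = cossim(candidate, A)
                better = best_val is None or val > best_val
            if better:
                best_val = val
                best = (perm, np.asarray(signs))
    return best


def apply_alignment(M, permutation, signs) -> np.ndarray:
    """Apply a column permutation and sign vector to a matrix."""
    M = np.asarray(M, dtype=float)
    return M[:, list(permutation)] * np.asarray(signs)


def index_of_sparseness(pev_sparse: float, pev_pca: float, ps: float) -> float:
    """Index of sparseness ``IS = PEV_sparse * PEV_pca * PS``."""
    return float(pev_sparse) * float(pev_pca) * float(ps)


def r_inf_squared(omega: float, c: float) -> float:
    """Limiting squared cosine between estimated and true leading eigenvector.

    ``omega`` is the limiting signal-to-noise ratio and ``c`` the limit of
    J/I.  Equals 1 iff ``c = 0``: with proportionally many variables the
    ordinary PCA eigenvector is an inconsistent estimate.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if c < 0:
        raise ValueError("c must be nonnegative")
    return max(omega**2 - c, 0.0) / (omega**2 + c * omega)
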