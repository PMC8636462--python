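"""Sparse loadings by simple-structure rotation followed by thresholding.

The rotational freedom of the low-rank model, ``T P' = T (Q^{-1})' (P Q)'``
for any non-singular ``Q``, leaves the fit unchanged while redistributing
loading mass.  Two classic criteria are provided:

Varimax
    Orthogonal ``Q`` maximizing the summed per-component variance of the
    squared loadings, driving loadings toward 0/1 structure.  Implemented
    with cyclic pairwise planar (Jacobi) rotations; optional Kaiser row
    normalization.

Simplimax
    Oblique ``Q`` bringing the rotated loadings as close as possible, in
    least squares, to an (unspecified) matrix with a given number ``m`` of
    zeros.  Alternating least squares over the target and the transform,
    with multiple random starts plus a Varimax start, keeping the best loss.

Neither rotation produces exact zeros; :func:`threshold_to_sparsity` zeroes
the smallest-magnitude rotated loadings to reach a requested sparsity
proportion.  The practice is deliberately ad hoc — scores are not
re-estimated and surviving loadings keep their rotated values — because that
is how thresholding is applied in everyday use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .rng import resolve_rng

__all__ = [
    "RotationResult",
    "ThresholdedLoadings",
    "varimax",
    "varimax_criterion",
    "simplimax",
    "threshold_to_sparsity",
]


@dataclass
class RotationResult:
    """A rotated solution: transform Q, rotated loadings PQ, rotated scores T(Q^{-1})'."""

    Q: np.ndarray
    rotated_loadings: np.ndarray
    rotated_scores: np.ndarray | None
    criterion_value: float
    n_starts_used: int = 1
    converged: bool = True


@dataclass
class ThresholdedLoadings:
    """Loadings with exact zeros introduced by magnitude thresholding."""

    loadings: np.ndarray
    zero_mask: np.ndarray
    proportion_sparsity: float


def varimax_criterion(P: np.ndarray) -> float:
    """Sum over components of the variance of the squared loadings."""
    sq = np.asarray(P, dtype=float) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax(
    P,
    scores: np.ndarray | None = None,
    normalize: bool = False,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RotationResult:
    """Varimax rotation by cyclic pairwise planar rotations.

    Parameters
    ----------
    P : ndarray (J, K)
        Loadings to rotate.
    scores : ndarray (I, K), optional
        Scores to counter-rotate (``T Q`` for orthogonal Q).
    normalize : bool
        Kaiser row normalization: rows are scaled to unit length before
        rotation and the scaling undone afterwards.  Off by default.
    tol : float
        Convergence when the criterion gain over a full sweep falls below
        this value.
    max_iter : int
        Maximum number of full sweeps over all column pairs.
    """
    P = np.asarray(P, dtype=float)
    J, K = P.shape
    if K < 2:
        warnings.warn("varimax with a single component is the identity rotation")
        Q = np.eye(K)
        return RotationResult(
            Q=Q,
            rotated_loadings=P.copy(),
            rotated_scores=None if scores is None else np.asarray(scores, float).copy(),
            criterion_value=varimax_criterion(P),
        )

    if normalize:
        h = np.linalg.norm(P, axis=1)
        h[h == 0] = 1.0
        L = P / h[:, None]
    else:
        L = P.copy()

    Q = np.eye(K)
    crit = varimax_criterion(L)
    converged = False
    for _ in range(max_iter):
        for a in range(K - 1):
            for b in range(a + 1, K):
                x, y = L[:, a], L[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (J * np.dot(u, v) - u.sum() * v.sum())
                den = J * (np.dot(u, u) - np.dot(v, v)) - (u.sum() ** 2 - v.sum() ** 2)
                theta = 0.25 * np.arctan2(num, den)
                if abs(theta) < 1e-15:
                    continue
                c, s = np.cos(theta), np.sin(theta)
                rot = np.array([[c, -s], [s, c]])
                L[:, [a, b]] = L[:, [a, b]] @ rot
                Q[:, [a, b]] = Q[:, [a, b]] @ rot
        new_crit = varimax_criterion(L)
        if new_crit - crit < tol:
            crit = max(new_crit, crit)
            converged = True
            break
        crit = new_crit
    if normalize:
        L = L * h[:, None]
        crit = varimax_criterion(L)
    rotated_scores = None if scores is None else np.asarray(scores, float) @ Q
    return RotationResult(
        Q=Q,
        rotated_loadings=L,
        rotated_scores=rotated_scores,
        criterion_value=crit,
        converged=converged,
    )


def _zero_smallest(L: np.ndarray, m: int) -> np.ndarray:
    """Copy of L with its m smallest-magnitude entries (globally) zeroed."""
    B = L.copy()
    if m == 0:
        return B
    order = np.argsort(np.abs(B).ravel(order="F"), kind="stable")[:m]
    cols, rows = np.divmod(order, B.shape[0])
    B[rows, cols] = 0.0
    return B


def _normalize_transform(Q: np.ndarray) -> np.ndarray:
    # Scale columns of Q so that diag((Q'Q)^{-1}) = 1, i.e. the columns of
    # (Q')^{-1} — the score-side transform — have unit norm.  Removes the
    # scale indeterminacy of the oblique ALS.
    M = scipy.linalg.inv(Q.T)
    scale = np.linalg.norm(M, axis=0)
    return Q * scale


def simplimax(
    P,
    m: int,
    scores: np.ndarray | None = None,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | np.random.Generator | None = 0,
) -> RotationResult:
    """Simplimax oblique rotation toward a matrix with ``m`` zeros.

    Alternates between the target update (zero the ``m`` smallest-magnitude
    rotated entries) and a least-squares transform update, normalized so
    that ``diag((Q'Q)^{-1}) = 1``.  The algorithm is prone to local optima;
    ``n_starts`` random non-singular starts plus one Varimax start are run
    and the best loss kept.
    """
    P = np.asarray(P, dtype=float)
    J, K = P.shape
    if not 0 <= m <= J * K - K:
        raise ValueError(
            f"m={m} must lie in [0, J*K-K]={J * K - K} to leave a nonzero per column"
        )
    rng = resolve_rng(seed)
    if m == 0:
        return RotationResult(
            Q=np.eye(K),
            rotated_loadings=P.copy(),
            rotated_scores=None if scores is None else np.asarray(scores, float).copy(),
            criterion_value=0.0,
            n_starts_used=1,
        )

    starts: list[np.ndarray] = [varimax(P).Q]
    while len(starts) < n_starts + 1:
        cand = rng.standard_normal((K, K))
        if abs(np.linalg.det(cand)) > 1e-8:
            starts.append(cand)

    best_loss = np.inf
    best_Q = np.eye(K)
    for Q0 in starts:
        Q = _normalize_transform(Q0)
        prev_loss = np.inf
        for _ in range(max_iter):
            L = P @ Q
            B = _zero_smallest(L, m)
            loss = float(np.sum((L - B) ** 2))
            if loss > prev_loss + 1e-15:
                # normalization bumped the loss: keep the previous iterate
                Q = prev_Q
                loss = prev_loss
                break
            if prev_loss - loss < tol:
                break
            prev_loss, prev_Q = loss, Q
            Q_new, *_ = scipy.linalg.lstsq(P, B)
            try:
                Q = _normalize_transform(Q_new)
            except scipy.linalg.LinAlgError:
                break
        if loss < best_loss:
            best_loss = loss
            best_Q = Q
    L = P @ best_Q
    rotated_scores = (
        None
        if scores is None
        else np.asarray(scores, float) @ scipy.linalg.inv(best_Q).T
    )
    return RotationResult(
        Q=best_Q,
        rotated_loadings=L,
        rotated_scores=rotated_scores,
        criterion_value=best_loss,
        n_starts_used=len(starts),
    )


def threshold_to_sparsity(
    P, ps: float, per_column: bool = False
) -> ThresholdedLoadings:
    """Zero the smallest-magnitude loadings to reach sparsity proportion ``ps``.

    Globally zeroes the ``floor(ps * J * K)`` smallest entries (ties broken
    by column-major index); with ``per_column`` the count is split evenly per
    component.  Raises if any column would lose all its nonzeros.
    """
    P = np.asarray(P, dtype=float)
    J, K = P.shape
    if not 0 <= ps < 1:
        raise ValueError("ps must lie in [0, 1)")
    n_zero = int(np.floor(ps * J * K))
    mask = np.zeros((J, K), dtype=bool)
    if per_column:
        base, extra = divmod(n_zero, K)
        for k in range(K):
            nk = base + (1 if k < extra else 0)
            order = np.argsort(np.abs(P[:, k]), kind="stable")
            mask[order[:nk], k] = True
    elif n_zero:
        flat = np.abs(P).ravel(order="F")
        order = np.argsort(flat, kind="stable")[:n_zero]
        cols, rows = np.divmod(order, J)
        mask[rows, cols] = True
    if np.any(mask.sum(axis=0) == J):
        raise ValueError(
            f"ps={ps} would zero an entire component; lower the sparsity proportion"
        )
    out = P.copy()
    out[mask] = 0.0
    return ThresholdedLoadings(
        loadings=out, zero_mask=mask, proportion_sparsity=n_zero / (J * K)
    )
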