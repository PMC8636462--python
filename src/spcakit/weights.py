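"""Sparse component weights: SPCA (elastic net), pathSPCA (greedy
cardinality), and GPower (penalized power method).

These methods sparsify the weights ``W`` that form the scores ``T = X W``,
so that each derived variable is a combination of only a few observed
variables — the summarization use of PCA.

SPCA
    Alternating minimization of
    ``||X - X W P'||_F^2 + lam2 * sum_k ||w_k||^2 + sum_k lam1_k ||w_k||_1``
    with ``P'P = I``.  The weight update is an elastic-net regression of
    each component score on the variables (cyclic coordinate descent); the
    loading update is an orthogonal Procrustes problem with closed-form
    solution.

pathSPCA
    Greedy forward selection for ``max_{||w||<=1} ||X w||^2 - rho ||w||_0``:
    starting from the highest-variance variable, repeatedly add the index
    that maximizes the leading eigenvalue of the covariance submatrix on the
    augmented support; the weight vector is the leading unit eigenvector on
    the final support.

GPower
    ``max_{||w||=1} ||X w|| - lam ||w||_1`` solved through the equivalent
    I-dimensional problem ``max_{||z||<=1} ||S(X'z, lam)||^2`` by power-type
    iterations; the soft-threshold pattern gives the support, and the final
    within-support weights come from ordinary PCA on the retained columns.

All fitted weight columns are unit-norm and scores satisfy ``T = X W`` on
the original data; loadings for explained-variance reporting are the least
squares ``P = X' T (T'T)^{-1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pca_core import (
    ComponentModel,
    as_matrix,
    least_squares_loadings,
    procrustes_rotation,
    soft_threshold,
    truncated_svd,
    warn_nonconvergence,
)
from .rsvd import PenaltySpec

__all__ = [
    "SupportSet",
    "elastic_net_cd",
    "spca_zou_fit",
    "pathspca_fit",
    "gpower_rank1",
    "gpower_fit",
]


@dataclass
class SupportSet:
    """An ordered set of variable positions carrying nonzero weight."""

    indices: tuple
    n_variables: int

    @property
    def complement(self) -> tuple:
        members = set(self.indices)
        return tuple(j for j in range(self.n_variables) if j not in members)

    @property
    def size(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# SPCA (elastic net regularization)
# ---------------------------------------------------------------------------

def _cd_sweeps(G, g, w, diag, lam1, lam2, tol, max_iter):
    # Gram-space cyclic coordinate descent; g tracks X'y - G w.
    J = w.shape[0]
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(J):
            wj_old = w[j]
            rho = g[j] + diag[j] * wj_old
            aj = np.abs(rho) - lam1 / 2.0
            wj_new = np.sign(rho) * aj / (diag[j] + lam2) if aj > 0 else 0.0
            delta = wj_new - wj_old
            if delta != 0.0:
                g -= G[:, j] * delta
                w[j] = wj_new
                if np.abs(delta) > max_delta:
                    max_delta = np.abs(delta)
        scale = np.max(np.abs(w))
        if max_delta < tol * (scale if scale > 1.0 else 1.0):
            break
    return w


try:  # compiled kernel: the CD inner loop is the hot path of SPCA
    from numba import njit

    _cd_sweeps = njit(cache=False)(_cd_sweeps)
except ImportError:  # pragma: no cover - numba is an optional speedup
    pass


def elastic_net_cd(
    X,
    y,
    lam1: float,
    lam2: float,
    tol: float = 1e-9,
    max_iter: int = 10_000,
    w0: np.ndarray | None = None,
) -> np.ndarray:
    """Cyclic coordinate descent for
    ``min_w ||y - X w||^2 + lam2 ||w||^2 + lam1 ||w||_1``.

    The coordinate update is
    ``w_j = S(x_j'(y - X_{-j} w_{-j}), lam1/2) / (x_j'x_j + lam2)``;
    at a solution the KKT conditions hold: ``|2 x_j' r| <= lam1`` for zero
    coordinates and ``2 x_j' r = 2 lam2 w_j + lam1 sign(w_j)`` otherwise.
    """
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be nonnegative")
    values = as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(values).all() and np.isfinite(y).all()):
        raise ValueError("non-finite input")
    J = values.shape[1]
    G = values.T @ values
    Xty = values.T @ y
    w = np.zeros(J) if w0 is None else np.asarray(w0, dtype=float).copy()
    g = Xty - G @ w
    return _cd_sweeps(G, g, w, np.diag(G).copy(), float(lam1), float(lam2),
                      float(tol), int(max_iter))


def _enet_gram(G, Xty, lam1, lam2, tol, max_iter, w0=None):
    w = np.zeros(G.shape[0]) if w0 is None else np.asarray(w0, dtype=float).copy()
    g = Xty - G @ w
    return _cd_sweeps(G, g, w, np.diag(G).copy(), float(lam1), float(lam2),
                      float(tol), int(max_iter))


def _enet_bisect_cardinality(G, Xty, r_target, lam2, tol, max_iter, steps, w0=None):
    """Bisect lam1 so the elastic-net solution has r_target nonzeros."""
    lo = 0.0
    hi = 2.0 * float(np.max(np.abs(Xty))) + 1e-12  # all-zero above this
    best = None
    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        w = _enet_gram(G, Xty, mid, lam2, tol, max_iter, w0=w0)
        nnz = int(np.count_nonzero(w))
        if best is None or abs(nnz - r_target) < abs(best[1] - r_target):
            best = (w, nnz, mid)
        if nnz == r_target:
            break
        if nnz > r_target:
            lo = mid
        else:
            hi = mid
    return best


def spca_zou_fit(
    X,
    K: int,
    penalty: PenaltySpec,
    tol: float = 1e-7,
    max_alt: int = 200,
) -> ComponentModel:
    """Sparse weights by alternating elastic-net regressions and a
    Procrustes loading update.

    ``penalty.ridge`` is the shared ridge ``lam2`` (defaulting to ``1e-6``
    when I > J and ``1`` otherwise, since with more variables than
    observations the lasso alone selects at most I of them);
    ``penalty.cardinality`` triggers per-component bisection on ``lam1_k``,
    otherwise ``penalty.lam`` is used directly for every component.
    """
    values = as_matrix(X)
    I, J = values.shape
    lam2 = penalty.ridge
    if lam2 == 0.0:
        lam2 = 1e-6 if I > J else 1.0
    svd = truncated_svd(values, K)
    P = svd.V.copy()
    W = svd.V.copy()
    G = values.T @ values
    cd_tol, cd_iter = 1e-9, 2_000

    def objective(W, P, lam1s):
        fit = float(np.sum((values - values @ W @ P.T) ** 2))
        pen = lam2 * float(np.sum(W**2)) + float(
            np.sum(lam1s * np.sum(np.abs(W), axis=0))
        )
        return fit + pen

    lam1s = np.full(K, penalty.lam)
    history: list[float] = []
    prev = None
    converged = False
    W_prev = None
    supports_prev = None
    tune_lam = penalty.cardinality is not None
    for _ in range(max_alt):
        for k in range(K):
            Xty = G @ P[:, k]  # X'(X p_k): regress the k-th score on X
            if tune_lam:
                w, _, lam_k = _enet_bisect_cardinality(
                    G, Xty, penalty.cardinality, lam2, cd_tol, cd_iter,
                    penalty.search_steps, w0=W[:, k],
                )
                lam1s[k] = lam_k
            else:
                w = _enet_gram(G, Xty, lam1s[k], lam2, cd_tol, cd_iter, w0=W[:, k])
            if not np.any(w):
                raise ValueError(
                    f"component {k} collapsed to the zero vector; lower the penalty"
                )
            W[:, k] = w
        if tune_lam:
            # re-bisecting lam1 every pass cycles; once the selected
            # supports stop moving, freeze the penalties so the remaining
            # alternation is plain block descent (monotone, convergent)
            supports = tuple(frozenset(np.nonzero(W[:, k])[0]) for k in range(K))
            if supports == supports_prev:
                tune_lam = False
            supports_prev = supports
        P = procrustes_rotation(values.T @ (values @ W))
        obj = objective(W, P, lam1s)
        history.append(obj)
        obj_still = prev is not None and abs(prev - obj) < tol * max(abs(prev), 1.0)
        w_still = W_prev is not None and float(np.max(np.abs(W - W_prev))) < 1e-7 * max(
            1.0, float(np.max(np.abs(W)))
        )
        if (obj_still and not tune_lam) or w_still:
            converged = True
            break
        prev = obj
        W_prev = W.copy()
    if not converged:
        warn_nonconvergence("spca_zou_fit", max_alt)

    norms = np.linalg.norm(W, axis=0)
    W = W / norms
    T = values @ W
    loadings = least_squares_loadings(values, T)
    return ComponentModel(
        scores=T,
        loadings=loadings,
        weights=W,
        n_components=K,
        method="spca",
        extras={"lam1": lam1s.copy(), "lam2": lam2, "objective_history": history},
    )


# ---------------------------------------------------------------------------
# pathSPCA (greedy cardinality-penalized variance maximization)
# ---------------------------------------------------------------------------

def _leading_eig(C_sub: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(C_sub)
    return float(vals[-1]), vecs[:, -1]


def greedy_support(C: np.ndarray, r: int) -> list[int]:
    """Greedy forward-selection path on a covariance matrix.

    Starts from the maximum-variance variable; each step adds the index
    maximizing the leading eigenvalue of the covariance submatrix on the
    augmented support.
    """
    J = C.shape[0]
    support = [int(np.argmax(np.diag(C)))]
    while len(support) < r:
        best_j, best_val = None, -np.inf
        for j in range(J):
            if j in support:
                continue
            idx = support + [j]
            val, _ = _leading_eig(C[np.ix_(idx, idx)])
            if val > best_val:
                best_val, best_j = val, j
        support.append(best_j)
    return support


def pathspca_fit(X, K: int, r: int) -> ComponentModel:
    """Sparse weights by the greedy cardinality path, one component at a
    time with least-squares rank-one deflation between components."""
    values = as_matrix(X)
    I, J = values.shape
    if not 1 <= r <= J:
        raise ValueError(f"cardinality r={r} out of range [1, {J}]")
    residual = values.copy()
    W = np.zeros((J, K))
    supports = []
    for k in range(K):
        C = residual.T @ residual
        support = greedy_support(C, r)
        _, v = _leading_eig(C[np.ix_(support, support)])
        # deterministic sign: largest-magnitude entry positive
        jmax = int(np.argmax(np.abs(v)))
        if v[jmax] < 0:
            v = -v
        w = np.zeros(J)
        w[support] = v
        W[:, k] = w
        supports.append(SupportSet(indices=tuple(support), n_variables=J))
        t = residual @ w
        p = residual.T @ t / float(t @ t)
        residual = residual - np.outer(t, p)
    T = values @ W
    loadings = least_squares_loadings(values, T)
    return ComponentModel(
        scores=T,
        loadings=loadings,
        weights=W,
        n_components=K,
        method="pathspca",
        extras={"supports": supports, "cardinality": r},
    )


# ---------------------------------------------------------------------------
# GPower (lasso-penalized power method)
# ---------------------------------------------------------------------------

def gpower_rank1(
    X,
    lam: float,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> tuple[np.ndarray, SupportSet]:
    """One GPower component: power iterations on
    ``max_{||z||<=1} ||S(X'z, lam)||^2``.

    Returns the unit sparse weight vector and its support.  ``lam`` must be
    below ``max_j ||x_j||``, else the soft threshold eliminates every
    variable for every unit ``z``.
    """
    values = as_matrix(X)
    col_norms = np.linalg.norm(values, axis=0)
    jstar = int(np.argmax(col_norms))
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if lam >= col_norms[jstar]:
        raise ValueError(
            f"penalty lam={lam:g} >= max_j ||x_j|| = {col_norms[jstar]:g} "
            "eliminates all variables"
        )
    z = values[:, jstar] / col_norms[jstar]
    converged = False
    for _ in range(max_iter):
        g = soft_threshold(values.T @ z, lam)
        Xg = values @ g
        norm = np.linalg.norm(Xg)
        if norm == 0:
            break
        z_new = Xg / norm
        # converge on the iterate, not the objective: the objective
        # plateaus quadratically in the angle and stops too early
        if float(np.max(np.abs(z_new - z))) < tol:
            z = z_new
            converged = True
            break
        z = z_new
    if not converged:
        warn_nonconvergence("gpower_rank1", max_iter)
    g = soft_threshold(values.T @ z, lam)
    norm = np.linalg.norm(g)
    if norm == 0:
        raise ValueError("penalty eliminated all variables at the final iterate")
    w = g / norm
    jmax = int(np.argmax(np.abs(w)))
    if w[jmax] < 0:
        w = -w
    support = SupportSet(
        indices=tuple(np.nonzero(w)[0].tolist()), n_variables=values.shape[1]
    )
    return w, support


def _gpower_support_for_cardinality(values, r, tol, max_iter, steps):
    """Bisect lam in (0, max_j ||x_j||) for a support of size r."""
    col_max = float(np.max(np.linalg.norm(values, axis=0)))
    lo, hi = 0.0, col_max * (1.0 - 1e-12)
    best = None
    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        try:
            w, support = gpower_rank1(values, mid, tol, max_iter)
        except ValueError:
            hi = mid
            continue
        nnz = support.size
        if best is None or abs(nnz - r) < abs(best[1].size - r):
            best = (w, support, mid)
        if nnz == r:
            break
        if nnz > r:
            lo = mid
        else:
            hi = mid
    if best is None:  # pragma: no cover - defensive
        raise RuntimeError("bisection failed to find any feasible penalty")
    if best[1].size != r:
        warnings.warn(
            f"bisection reached support size {best[1].size} instead of the "
            f"requested {r}; keeping the nearest achievable",
            RuntimeWarning,
        )
    return best


def gpower_fit(
    X,
    K: int,
    penalty: PenaltySpec,
    tol: float = 1e-9,
    max_iter: int = 5000,
) -> ComponentModel:
    """Multi-component GPower with least-squares rank-one deflation.

    Per component the support is found by :func:`gpower_rank1` (with ``lam``
    bisected to hit ``penalty.cardinality`` when given); the within-support
    weights are then the leading right singular vector of the retained
    columns of the current residual — ordinary PCA on the selected
    variables — embedded into a unit J-vector.
    """
    values = as_matrix(X)
    I, J = values.shape
    residual = values.copy()
    W = np.zeros((J, K))
    supports = []
    for k in range(K):
        if penalty.cardinality is not None:
            if penalty.cardinality == J:
                support = SupportSet(indices=tuple(range(J)), n_variables=J)
            else:
                _, support, _ = _gpower_support_for_cardinality(
                    residual, penalty.cardinality, tol, max_iter, penalty.search_steps
                )
        else:
            _, support = gpower_rank1(residual, penalty.lam, tol, max_iter)
        idx = list(support.indices)
        sub = residual[:, idx]
        v = truncated_svd(sub, 1).V[:, 0]
        w = np.zeros(J)
        w[idx] = v
        W[:, k] = w
        supports.append(support)
        t = residual @ w
        p = residual.T @ t / float(t @ t)
        residual = residual - np.outer(t, p)
    T = values @ W
    loadings = least_squares_loadings(values, T)
    return ComponentModel(
        scores=T,
        loadings=loadings,
        weights=W,
        n_components=K,
        method="gpower",
        extras={"supports": supports, "penalty": penalty},
    )
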