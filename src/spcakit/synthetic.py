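"""Synthetic data with planted sparse component structure.

Three generating regimes are provided, each starting from the truncated SVD
``X0 = U D V'`` of an i.i.d. standard-normal matrix:

``alg1-sparseP``
    Sparse component loadings: ``P = sparsify(V D)``, orthonormal scores
    ``T = U``, signal ``T P'``.
``alg2-sparseW``
    Sparse component weights: ``W = sparsify(V)`` with unit-norm columns,
    scores ``T = X0 W``, loadings by least squares ``P = X0' T (T'T)^{-1}``,
    signal ``T P'``.
``alg3-double``
    Loadings and weights simultaneously sparse with disjoint (hence
    orthogonal) supports: ``V_s = sparsify(V)`` disjoint + unit-norm.  Under
    the sparse-loadings scenario ``P = V_s D`` and ``W = V_s D^{-1}``; under
    the sparse-weights scenario ``P = W = V_s``.  Scores ``T = X0 W``.

Additive noise is i.i.d. normal, column-centered, made Frobenius-orthogonal
to the signal, and rescaled so that the realized proportion of variance
accounted for (VAF) by the signal equals the target exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .pca_core import DataMatrix, truncated_svd

__all__ = [
    "GeneratedDataset",
    "REGIMES",
    "sparsify",
    "scale_noise_to_vaf",
    "generate",
    "condition_seed",
]

REGIMES = ("alg1-sparseP", "alg2-sparseW", "alg3-double")


@dataclass
class GeneratedDataset:
    """A generated dataset plus its ground truth."""

    X: DataMatrix
    T_true: np.ndarray
    P_true: np.ndarray
    W_true: np.ndarray | None
    E: np.ndarray
    vaf: float
    ps: float
    regime: str
    scenario: str | None
    zero_mask_P: np.ndarray | None
    zero_mask_W: np.ndarray | None
    seed: int

    @property
    def signal(self) -> np.ndarray:
        return self.T_true @ self.P_true.T

    @property
    def sparse_target(self) -> np.ndarray:
        """The matrix on which sparsity was imposed (P or W)."""
        if self.regime == "alg1-sparseP":
            return self.P_true
        if self.regime == "alg2-sparseW":
            return self.W_true
        return self.P_true if self.scenario == "sparse-P" else self.W_true

    @property
    def sparse_zero_mask(self) -> np.ndarray:
        if self.regime == "alg1-sparseP":
            return self.zero_mask_P
        if self.regime == "alg2-sparseW":
            return self.zero_mask_W
        return self.zero_mask_P if self.scenario == "sparse-P" else self.zero_mask_W


def condition_seed(regime, I, J, K, vaf, ps, replicate, master_seed) -> int:
    """Stable per-dataset seed derived from the condition and a master seed.

    Hash-based so that adding or reordering conditions never changes the
    stream any other dataset sees.
    """
    key = f"{regime}|{I}|{J}|{K}|{float(vaf):.10g}|{float(ps):.10g}|{replicate}|{master_seed}"
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**63)


def sparsify(
    M: np.ndarray,
    ps: float,
    disjoint: bool = False,
    rng: np.random.Generator | None = None,
    unit_norm: bool = False,
    magnitude_based: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero a proportion ``ps`` of the entries of ``M``, stratified by column.

    Zero positions are uniform at random within each column (or, with
    ``magnitude_based``, the smallest-magnitude entries), with every column
    receiving the same nonzero count up to one.  ``disjoint`` places the
    nonzero row-slots of different columns without overlap, so the sparse
    columns are mutually orthogonal.

    Returns
    -------
    (sparse, zero_mask)
        The sparsified copy and a boolean mask of the zeroed entries.
    """
    if rng is None:
        rng = np.random.default_rng()
    M = np.asarray(M, dtype=float)
    J, K = M.shape
    if not 0 <= ps < 1:
        raise ValueError("sparsity proportion must lie in [0, 1)")
    total_zeros = int(round(ps * J * K))
    base, extra = divmod(total_zeros, K)
    zeros_per_col = np.full(K, base, dtype=int)
    zeros_per_col[:extra] += 1
    nonzeros_per_col = J - zeros_per_col
    if np.any(nonzeros_per_col < 1):
        raise ValueError(f"ps={ps} leaves no nonzero entry in some column")
    if disjoint and nonzeros_per_col.sum() > J:
        raise ValueError(
            f"disjoint supports infeasible: {nonzeros_per_col.sum()} nonzero "
            f"slots exceed {J} rows (increase ps)"
        )

    out = M.copy()
    mask = np.zeros((J, K), dtype=bool)
    if disjoint:
        rows = rng.permutation(J)
        start = 0
        for k in range(K):
            keep = rows[start : start + nonzeros_per_col[k]]
            start += nonzeros_per_col[k]
            col_mask = np.ones(J, dtype=bool)
            col_mask[keep] = False
            mask[:, k] = col_mask
    else:
        for k in range(K):
            if magnitude_based:
                order = np.argsort(np.abs(M[:, k]), kind="stable")
                zero_rows = order[: zeros_per_col[k]]
            else:
                zero_rows = rng.choice(J, size=zeros_per_col[k], replace=False)
            mask[zero_rows, k] = True
    out[mask] = 0.0
    if unit_norm:
        norms = np.linalg.norm(out, axis=0)
        if np.any(norms == 0):
            raise ValueError("a column lost all mass during sparsification")
        out /= norms
    return out, mask


def scale_noise_to_vaf(
    signal: np.ndarray, vaf: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw noise and scale it so the signal accounts for exactly ``vaf``.

    The noise starts i.i.d. standard normal, is column-centered (the signal
    is column-centered by construction, so X stays centered) and projected
    to be Frobenius-orthogonal to the signal; the realized
    ``||signal||^2 / ||signal + E||^2`` then equals ``vaf`` exactly.
    """
    if not 0 < vaf <= 1:
        raise ValueError("vaf must lie in (0, 1]")
    signal = np.asarray(signal, dtype=float)
    sig2 = float(np.sum(signal**2))
    if vaf == 1.0:
        return np.zeros_like(signal)
    if sig2 == 0:
        raise ValueError("zero signal cannot attain vaf < 1")
    E0 = rng.standard_normal(signal.shape)
    E0 -= E0.mean(axis=0, keepdims=True)
    E0 -= (np.sum(E0 * signal) / sig2) * signal
    c = np.sqrt((1.0 - vaf) / vaf * sig2 / np.sum(E0**2))
    return c * E0


def generate(
    regime: str,
    I: int,
    J: int,
    K: int,
    vaf: float,
    ps: float,
    seed: int,
    scenario: str = "sparse-P",
) -> GeneratedDataset:
    """Generate one dataset under the requested regime.

    Parameters
    ----------
    regime : {"alg1-sparseP", "alg2-sparseW", "alg3-double"}
    I, J, K : int
        Observations, variables, components (K <= min(I, J)).
    vaf : float in (0, 1]
        Proportion of the total sum of squares carried by the signal.
    ps : float in [0, 1)
        Proportion of zeros planted in the sparse factor matrix.
    seed : int
        Seeds the whole construction; same arguments -> identical dataset.
    scenario : {"sparse-P", "sparse-W"}
        Only used by ``alg3-double``: which factor the analysis model treats
        as sparse (the planted supports are the same disjoint set).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if scenario not in ("sparse-P", "sparse-W"):
        raise ValueError("scenario must be 'sparse-P' or 'sparse-W'")
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((I, J))
    X0 -= X0.mean(axis=0, keepdims=True)
    svd = truncated_svd(X0, K)
    U, D, V = svd.U, svd.D, svd.V

    zero_mask_P = zero_mask_W = None
    if regime == "alg1-sparseP":
        P, zero_mask_P = sparsify(V * D, ps, rng=rng)
        T = U
        W = None
        signal = T @ P.T
    elif regime == "alg2-sparseW":
        W, zero_mask_W = sparsify(V, ps, rng=rng, unit_norm=True)
        T = X0 @ W
        P = X0.T @ (T @ np.linalg.inv(T.T @ T))
        signal = T @ P.T
    else:  # alg3-double: disjoint supports, orthonormal sparse factor
        Vs, mask = sparsify(V, ps, disjoint=True, rng=rng, unit_norm=True)
        if scenario == "sparse-P":
            P = Vs * D
            W = Vs / D
        else:
            P = Vs
            W = Vs
        zero_mask_P = zero_mask_W = mask
        T = X0 @ W
        signal = T @ P.T

    E = scale_noise_to_vaf(signal, vaf, rng)
    X = signal + E
    X -= X.mean(axis=0, keepdims=True)  # no-op up to rounding: both terms centered
    return GeneratedDataset(
        X=DataMatrix(values=X, standardized=False),
        T_true=T,
        P_true=P,
        W_true=W,
        E=E,
        vaf=vaf,
        ps=ps,
        regime=regime,
        scenario=scenario if regime == "alg3-double" else None,
        zero_mask_P=zero_mask_P,
        zero_mask_W=zero_mask_W,
        seed=seed,
    )
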