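import itertools
import warnings

import numpy as np
import pytest

from spcakit import (
    PenaltySpec,
    elastic_net_cd,
    gpower_fit,
    gpower_rank1,
    pathspca_fit,
    pca_fit,
    spca_zou_fit,
    truncated_svd,
)
from spcakit.metrics import pev
from spcakit.weights import greedy_support


def kkt_enumeration_solution(X, y, lam1, lam2):
    """Independent oracle: solve the elastic net by enumerating sign patterns
    of the KKT system (feasible for tiny J)."""
    J = X.shape[1]
    for signs in itertools.product((-1, 0, 1), repeat=J):
        active = [j for j in range(J) if signs[j] != 0]
        w = np.zeros(J)
        if active:
            XA = X[:, active]
            sA = np.array([signs[j] for j in active], dtype=float)
            wA = np.linalg.solve(
                XA.T @ XA + lam2 * np.eye(len(active)),
                XA.T @ y - lam1 * sA / 2.0,
            )
            if not np.all(np.sign(wA) == sA):
                continue
            w[active] = wA
        r = y - X @ w
        inactive_ok = all(
            abs(2 * X[:, j] @ r) <= lam1 + 1e-9 for j in range(J) if signs[j] == 0
        )
        if inactive_ok:
            return w
    raise AssertionError("no consistent KKT sign pattern found")


class TestElasticNet:
    def test_large_lasso_gives_zero(self, rng):
        X = rng.standard_normal((12, 5))
        y = rng.standard_normal(12)
        lam1 = 2 * np.max(np.abs(X.T @ y)) * 1.01
        np.testing.assert_array_equal(elastic_net_cd(X, y, lam1, 0.5), 0)

    def test_unpenalized_orthonormal_design(self, rng):
        Q = np.linalg.qr(rng.standard_normal((10, 4)))[0]
        y = rng.standard_normal(10)
        np.testing.assert_allclose(elastic_net_cd(Q, y, 0.0, 0.0), Q.T @ y, atol=1e-8)

    @pytest.mark.parametrize("lam1,lam2", [(0.6, 0.3), (2.0, 0.0), (0.1, 1.5)])
    def test_matches_kkt_enumeration_oracle(self, rng, lam1, lam2):
        X = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        w_cd = elastic_net_cd(X, y, lam1, lam2, tol=1e-12)
        w_kkt = kkt_enumeration_solution(X, y, lam1, lam2)
        np.testing.assert_allclose(w_cd, w_kkt, atol=1e-6)

    def test_support_monotone_in_lasso_penalty(self, rng):
        X = rng.standard_normal((20, 8))
        y = rng.standard_normal(20)
        nnz = [
            np.count_nonzero(elastic_net_cd(X, y, lam1, 0.1))
            for lam1 in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 20.0)
        ]
        assert all(b <= a for a, b in zip(nnz, nnz[1:]))


class TestSPCA:
    def test_penalty_free_limit_spans_pca_subspace(self, rng):
        X = rng.standard_normal((40, 6))
        X -= X.mean(axis=0)
        m = spca_zou_fit(X, 2, PenaltySpec(mode="lasso", lam=0.0))
        V = truncated_svd(X, 2).V
        # principal angles between span(W) and span(V)
        qw = np.linalg.qr(m.weights)[0]
        qv = np.linalg.qr(V)[0]
        angles = np.arccos(np.clip(np.linalg.svd(qw.T @ qv, compute_uv=False), -1, 1))
        assert np.max(angles) < 1e-4

    def test_objective_nonincreasing_for_fixed_penalties(self, rng):
        X = rng.standard_normal((25, 8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = spca_zou_fit(X, 2, PenaltySpec(mode="lasso", lam=1.0, ridge=0.5))
        hist = m.extras["objective_history"]
        assert all(b <= a + 1e-8 for a, b in zip(hist, hist[1:]))

    def test_planted_one_sparse_weights_recovered(self):
        from spcakit.synthetic import generate

        ds = generate("alg2-sparseW", 60, 8, 2, vaf=1.0, ps=0.875, seed=11)
        m = spca_zou_fit(ds.X, 2, PenaltySpec(mode="cardinality", cardinality=1))
        est = {frozenset(np.nonzero(m.weights[:, k])[0]) for k in range(2)}
        true = {frozenset(np.nonzero(ds.W_true[:, k])[0]) for k in range(2)}
        assert est == true

    def test_collapsed_component_raises(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="penalty"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                spca_zou_fit(X, 2, PenaltySpec(mode="lasso", lam=1e4))

    def test_unit_weight_columns_and_consistent_scores(self, rng):
        X = rng.standard_normal((30, 6))
        m = spca_zou_fit(X, 2, PenaltySpec(mode="cardinality", cardinality=3))
        np.testing.assert_allclose(np.linalg.norm(m.weights, axis=0), 1.0, atol=1e-10)
        np.testing.assert_array_equal(m.scores, X @ m.weights)


class TestPathSPCA:
    def test_single_variable_support_is_max_variance_column(self, rng):
        X = rng.standard_normal((20, 6)) * np.array([1, 1, 3, 1, 1, 1.0])
        m = pathspca_fit(X, 1, 1)
        j = int(np.argmax(np.linalg.norm(X, axis=0)))
        assert np.nonzero(m.weights[:, 0])[0].tolist() == [j]

    def test_full_support_equals_leading_eigenvector(self, rng):
        X = rng.standard_normal((20, 6))
        m = pathspca_fit(X, 1, 6)
        v = truncated_svd(X, 1).V[:, 0]
        np.testing.assert_allclose(np.abs(m.weights[:, 0]), np.abs(v), atol=1e-8)

    def test_greedy_bounded_by_exhaustive_subset_oracle(self, rng):
        X = rng.standard_normal((25, 6))
        C = X.T @ X
        support = greedy_support(C, 3)
        greedy_val = np.linalg.eigvalsh(C[np.ix_(support, support)])[-1]
        best = max(
            np.linalg.eigvalsh(C[np.ix_(list(s), list(s))])[-1]
            for s in itertools.combinations(range(6), 3)
        )
        assert greedy_val <= best + 1e-10
        # at the path ends the greedy choice is exactly optimal
        assert greedy_support(C, 1)[0] == int(np.argmax(np.diag(C)))

    def test_greedy_objective_nondecreasing_in_cardinality(self, rng):
        X = rng.standard_normal((25, 7))
        C = X.T @ X
        vals = [
            np.linalg.eigvalsh(C[np.ix_(greedy_support(C, r), greedy_support(C, r))])[-1]
            for r in range(1, 8)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(vals, vals[1:]))

    def test_cardinality_out_of_range(self, rng):
        with pytest.raises(ValueError):
            pathspca_fit(rng.standard_normal((10, 4)), 1, 5)


class TestGPower:
    def test_zero_penalty_recovers_leading_singular_vector(self, rng):
        X = rng.standard_normal((12, 6))
        w, support = gpower_rank1(X, 0.0)
        v = truncated_svd(X, 1).V[:, 0]
        np.testing.assert_allclose(np.abs(w), np.abs(v), atol=1e-6)
        assert support.size == 6

    def test_dominant_column_survives_heavy_penalty(self, rng):
        X = rng.standard_normal((20, 5))
        X[:, 1] *= 20.0
        norms = np.linalg.norm(X, axis=0)
        w, support = gpower_rank1(X, norms[1] * 0.95)
        assert support.indices == (1,)
        np.testing.assert_allclose(np.abs(w), np.eye(5)[1], atol=1e-10)

    def test_penalty_eliminating_everything_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="eliminates"):
            gpower_rank1(X, np.max(np.linalg.norm(X, axis=0)) * 1.1)

    def test_support_monotone_in_penalty(self, rng):
        X = rng.standard_normal((30, 10))
        lam_max = np.max(np.linalg.norm(X, axis=0))
        sizes = [
            gpower_rank1(X, f * lam_max)[1].size
            for f in (0.0, 0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_single_component_zero_penalty_equals_pca(self, rng):
        X = rng.standard_normal((25, 6))
        X -= X.mean(axis=0)
        m = gpower_fit(X, 1, PenaltySpec(mode="lasso", lam=0.0))
        base = pca_fit(X, 1, "maxvar")
        np.testing.assert_allclose(
            np.abs(m.weights[:, 0]), np.abs(base.weights[:, 0]), atol=1e-6
        )

    def test_requested_cardinality_reached(self, rng):
        from spcakit.synthetic import generate

        ds = generate("alg2-sparseW", 50, 10, 2, vaf=0.95, ps=0.8, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = gpower_fit(ds.X, 2, PenaltySpec(mode="cardinality", cardinality=2))
        assert np.count_nonzero(m.weights) == 4

    def test_unit_weight_columns_and_exact_scores(self, rng):
        X = rng.standard_normal((30, 8))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = gpower_fit(X, 2, PenaltySpec(mode="cardinality", cardinality=3))
        np.testing.assert_allclose(np.linalg.norm(m.weights, axis=0), 1.0, atol=1e-10)
        np.testing.assert_array_equal(m.scores, X @ m.weights)


class TestPenaltyFreePEV:
    @pytest.mark.parametrize("method", ["spca", "pathspca", "gpower"])
    def test_pev_matches_ordinary_pca(self, rng, method):
        X = rng.standard_normal((40, 6))
        X -= X.mean(axis=0)
        base = pca_fit(X, 2)
        expected = pev(X, base.scores, base.loadings)
        if method == "spca":
            m = spca_zou_fit(X, 2, PenaltySpec(mode="lasso", lam=0.0))
        elif method == "pathspca":
            m = pathspca_fit(X, 2, 6)
        else:
            m = gpower_fit(X, 2, PenaltySpec(mode="lasso", lam=0.0))
        assert pev(X, m.scores, m.loadings) == pytest.approx(expected, abs=1e-6)
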