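import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spcakit import (
    center_scale,
    deflate,
    pca_fit,
    procrustes_rotation,
    soft_threshold,
    truncated_svd,
)
from spcakit.synthetic import generate


class TestCenterScale:
    def test_two_point_column(self):
        out = center_scale(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(
            out.values[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_idempotent(self, rng):
        once = center_scale(rng.standard_normal((20, 4)))
        twice = center_scale(once.values)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_columns_standardized(self, rng):
        out = center_scale(rng.standard_normal((15, 5)))
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_constant_column_names_offender(self):
        with pytest.raises(ValueError, match="v2"):
            center_scale(np.array([[1.0, 2.0], [3.0, 2.0]]), col_ids=["v1", "v2"])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            center_scale(np.array([[1.0, np.nan], [3.0, 2.0]]))

    def test_raw_recoverable(self, rng):
        raw = rng.standard_normal((10, 3)) * 5 + 2
        out = center_scale(raw)
        np.testing.assert_allclose(
            out.values * out.column_sds + out.column_means, raw, atol=1e-10
        )


class TestTruncatedSVD:
    def test_diagonal_matrix(self):
        out = truncated_svd(np.diag([3.0, 1.0]), 1)
        np.testing.assert_allclose(out.D, [3.0])
        np.testing.assert_allclose(out.V[:, 0], [1.0, 0.0], atol=1e-12)

    def test_exact_rank_k_reconstruction(self, rng):
        A = rng.standard_normal((9, 4)) @ rng.standard_normal((4, 6))
        out = truncated_svd(A, 4)
        np.testing.assert_allclose(out.U * out.D @ out.V.T, A, atol=1e-8)

    def test_residual_equals_discarded_singular_values(self, rng):
        # oracle: a full decomposition of the same matrix
        A = rng.standard_normal((8, 5))
        s_full = np.linalg.svd(A, compute_uv=False)
        out = truncated_svd(A, 3)
        resid = np.sum((A - out.U * out.D @ out.V.T) ** 2)
        np.testing.assert_allclose(resid, s_full[3] ** 2 + s_full[4] ** 2, atol=1e-8)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            truncated_svd(rng.standard_normal((5, 4)), 5)

    def test_sign_convention_deterministic(self, rng):
        A = rng.standard_normal((10, 6))
        a = truncated_svd(A, 4)
        b = truncated_svd(A.copy(), 4)
        assert np.array_equal(a.V, b.V) and np.array_equal(a.U, b.U)
        # largest-magnitude entry of each V column is positive
        for k in range(4):
            assert a.V[np.argmax(np.abs(a.V[:, k])), k] > 0


class TestPCAFormulations:
    @pytest.mark.parametrize("formulation", ["ls-orthP", "ls-orthT", "maxvar"])
    def test_reconstructions_identical(self, small_standardized, formulation):
        ref = pca_fit(small_standardized, 3, "ls-orthP").reconstruction()
        alt = pca_fit(small_standardized, 3, formulation).reconstruction()
        np.testing.assert_allclose(alt, ref, atol=1e-8)

    def test_score_orthogonality_constraints(self, small_standardized):
        I = small_standardized.n_obs
        m2 = pca_fit(small_standardized, 3, "ls-orthP")
        np.testing.assert_allclose(m2.loadings.T @ m2.loadings, np.eye(3), atol=1e-8)
        m3 = pca_fit(small_standardized, 3, "ls-orthT")
        np.testing.assert_allclose(
            m3.scores.T @ m3.scores, (I - 1) * np.eye(3), atol=1e-6
        )

    def test_scores_equal_x_times_weights(self, small_standardized):
        for formulation in ("ls-orthP", "ls-orthT", "maxvar"):
            m = pca_fit(small_standardized, 3, formulation)
            np.testing.assert_allclose(
                m.scores, small_standardized.values @ m.weights, atol=1e-8
            )

    def test_maxvar_on_perfectly_correlated_pair(self):
        x = np.linspace(-1, 1, 11)
        X = center_scale(np.column_stack([x, 2 * x + 1]))
        m = pca_fit(X, 1, "maxvar")
        np.testing.assert_allclose(
            np.abs(m.weights[:, 0]), [1 / np.sqrt(2)] * 2, atol=1e-10
        )

    def test_zero_singular_value_rejected_for_score_orthogonal_form(self):
        x = np.linspace(0, 1, 8)
        X = center_scale(np.column_stack([x, 3 * x]))  # rank 1 after scaling
        with pytest.raises(ValueError, match="singular"):
            pca_fit(X, 2, "ls-orthT")

    def test_deterministic_across_runs(self, small_standardized):
        a = pca_fit(small_standardized, 3)
        b = pca_fit(small_standardized, 3)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-12)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x, lam, expected", [(2.0, 0.5, 1.5), (-0.3, 0.5, 0.0), (-2.0, 0.5, -1.5)]
    )
    def test_examples(self, x, lam, expected):
        assert soft_threshold(np.array([x]), lam)[0] == pytest.approx(expected)

    def test_zero_lambda_is_identity(self, rng):
        x = rng.standard_normal(10)
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=20),
        st.floats(0, 50),
    )
    def test_shrinks_toward_zero_preserving_sign(self, xs, lam):
        x = np.array(xs)
        s = soft_threshold(x, lam)
        assert np.all(np.abs(s) <= np.abs(x) + 1e-12)
        assert np.all((s == 0) | (np.sign(s) == np.sign(x)))


class TestProcrustes:
    def test_identity(self):
        np.testing.assert_allclose(procrustes_rotation(np.eye(3)), np.eye(3))

    def test_orthogonal_input_is_fixed_point(self, rng):
        M = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        np.testing.assert_allclose(procrustes_rotation(M), M, atol=1e-10)

    def test_matches_grid_search_over_planar_rotations(self, rng):
        # oracle: fine grid over 2x2 rotations and reflections
        M = rng.standard_normal((2, 2))
        Q = procrustes_rotation(M)
        np.testing.assert_allclose(Q.T @ Q, np.eye(2), atol=1e-10)
        best = -np.inf
        for theta in np.linspace(0, 2 * np.pi, 6284):
            c, s = np.cos(theta), np.sin(theta)
            for R in (np.array([[c, -s], [s, c]]), np.array([[c, s], [s, -c]])):
                best = max(best, np.trace(R.T @ M))
        assert np.trace(Q.T @ M) >= best - 1e-6

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            procrustes_rotation(np.array([[np.inf, 0.0], [0.0, 1.0]]))


class TestDeflate:
    def test_exact_rank_one_removal(self, rng):
        t = rng.standard_normal(7)
        p = rng.standard_normal(4)
        np.testing.assert_allclose(deflate(np.outer(t, p), t, p), 0, atol=1e-12)

    def test_zero_score_is_noop(self, rng):
        X = rng.standard_normal((6, 3))
        np.testing.assert_array_equal(deflate(X, np.zeros(6), rng.standard_normal(3)), X)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            deflate(rng.standard_normal((6, 3)), np.zeros(5), np.zeros(3))

    def test_successive_deflation_of_noiseless_data_reaches_zero(self):
        ds = generate("alg1-sparseP", 40, 8, 2, vaf=1.0, ps=0.5, seed=3)
        X = ds.X.values
        for k in range(2):
            X = deflate(X, ds.T_true[:, k], ds.P_true[:, k])
        assert np.linalg.norm(X) < 1e-8
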