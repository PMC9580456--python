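"""Standardization, PCA/gram-matrix equivalence, HOSVD, axis selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unsupfe import (
    ExpressionMatrix,
    ExpressionTensor,
    hosvd,
    pca,
    select_axes,
    standardize_matrix,
    standardize_tensor,
)


def _matrix(values):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(values, [f"g{i}" for i in range(n)], [f"s{j}" for j in range(m)])


def _tensor(values):
    values = np.asarray(values, dtype=float)
    n, m, k = values.shape
    return ExpressionTensor(
        values,
        [f"g{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        [f"c{l}" for l in range(k)],
    )


class TestStandardizeMatrix:
    def test_single_column_arithmetic(self):
        # center (0,0,6) to (-2,-2,4), scale by sqrt(3/24)
        x = _matrix(np.column_stack([[0.0, 0.0, 6.0], [1.0, 2.0, 3.0]]))
        out = standardize_matrix(x)
        np.testing.assert_allclose(
            out.values[:, 0], [-0.70711, -0.70711, 1.41421], atol=1e-5
        )

    def test_postconditions_hold_on_counts(self, small_matrix):
        out = standardize_matrix(small_matrix)
        n = out.n_features
        np.testing.assert_allclose(out.values.sum(axis=0), 0.0, atol=1e-8 * n)
        np.testing.assert_allclose((out.values**2).sum(axis=0), n, atol=1e-8 * n)

    def test_idempotent_on_standardized_input(self, small_matrix):
        once = standardize_matrix(small_matrix)
        twice = standardize_matrix(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_column_error_names_sample(self):
        x = _matrix(np.column_stack([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="s0"):
            standardize_matrix(x)

    def test_log_transform_applied_before_scaling(self):
        x = _matrix([[1.0, 3.0], [3.0, 1.0], [7.0, 15.0]])
        out = standardize_matrix(x, log_transform=True, pseudocount=1.0)
        expected = np.log2(x.values + 1.0)
        expected -= expected.mean(axis=0)
        expected *= np.sqrt(3 / (expected**2).sum(axis=0))
        np.testing.assert_allclose(out.values, expected, atol=1e-12)


class TestStandardizeTensor:
    def test_fiber_arithmetic(self):
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [1.0, 2.0, 3.0]
        vals = np.tile(vals, (1, 2, 2))
        vals[:, 1, 1] = [4.0, 0.0, 1.0]
        out = standardize_tensor(_tensor(vals))
        np.testing.assert_allclose(
            out.values[:, 0, 0], [-1.22474, 0.0, 1.22474], atol=1e-5
        )

    def test_every_fiber_centered_and_scaled(self, rng):
        out = standardize_tensor(_tensor(rng.normal(size=(8, 3, 4))))
        np.testing.assert_allclose(out.values.sum(axis=0), 0.0, atol=1e-8 * 8)
        np.testing.assert_allclose((out.values**2).sum(axis=0), 8.0, atol=1e-8 * 8)

    def test_constant_fiber_error_reports_pair(self, rng):
        vals = rng.normal(size=(4, 2, 2))
        vals[:, 1, 0] = 2.5
        with pytest.raises(ValueError, match=r"\(s1, c0\)"):
            standardize_tensor(_tensor(vals))


class TestPCA:
    def test_rank_one_matrix_has_single_component(self, rng):
        a = rng.normal(size=6)
        b = np.array([1.0, -1.0, 2.0, -2.0])
        x = standardize_matrix(_matrix(np.outer(a, b)))
        dec = pca(x)
        assert np.sum(dec.eigenvalues > 1e-8) == 1
        assert dec.contributions[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_dense_gram_eigendecomposition(self, rng):
        x = standardize_matrix(_matrix(rng.normal(size=(6, 4))))
        dec = pca(x)
        gram = x.values @ x.values.T
        w, v = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1][: dec.n_components]
        np.testing.assert_allclose(dec.eigenvalues, w[order], atol=1e-8)
        for l in range(dec.n_components):
            ref = v[:, order[l]]
            got = dec.scores[:, l]
            assert min(np.max(np.abs(got - ref)), np.max(np.abs(got + ref))) < 1e-8

    def test_trace_conservation(self, small_matrix):
        x = standardize_matrix(small_matrix)
        dec = pca(x)
        assert dec.eigenvalues.sum() == pytest.approx(
            x.n_features * x.n_samples, rel=1e-10
        )

    def test_loading_orthogonality_scaled_by_eigenvalues(self, small_matrix):
        dec = pca(standardize_matrix(small_matrix))
        gram = dec.loadings.T @ dec.loadings
        np.testing.assert_allclose(gram, np.diag(dec.eigenvalues), atol=1e-8)

    def test_loadings_are_projected_data(self, small_matrix):
        x = standardize_matrix(small_matrix)
        dec = pca(x)
        np.testing.assert_allclose(dec.loadings, x.values.T @ dec.scores, atol=1e-8)

    def test_deterministic_sign_convention(self, small_matrix):
        x = standardize_matrix(small_matrix)
        a, b = pca(x), pca(x)
        np.testing.assert_array_equal(a.scores, b.scores)
        idx = np.argmax(np.abs(a.scores), axis=0)
        assert np.all(a.scores[idx, np.arange(a.n_components)] > 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n=st.integers(3, 20),
        m=st.integers(2, 20),
        seed=st.integers(0, 10_000),
    )
    def test_svd_route_equals_gram_route(self, n, m, seed):
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=(n, m))
        raw += rng.normal(size=(1, m))  # avoid near-constant columns
        x = standardize_matrix(_matrix(raw))
        dec = pca(x)
        gram = x.values @ x.values.T
        w = np.sort(np.linalg.eigvalsh(gram))[::-1][: dec.n_components]
        np.testing.assert_allclose(dec.eigenvalues, np.maximum(w, 0), atol=1e-7)


class TestHOSVD:
    def test_rank_one_tensor_core(self):
        a = np.array([3.0, 4.0]) / 5.0
        b = np.array([1.0, 0.0, 0.0])
        c = np.array([0.6, 0.8])
        t = _tensor(np.einsum("i,j,k->ijk", a, b, c))
        dec = hosvd(t)
        core = np.abs(dec.core)
        assert core.max() == pytest.approx(1.0, abs=1e-10)
        assert np.sum(core > 1e-8) == 1

    def test_factors_match_unfolding_svd_oracle(self, rng):
        vals = rng.normal(size=(3, 3, 3))
        dec = hosvd(_tensor(vals))
        for mode, factor in enumerate(
            (dec.factor_feature, dec.factor_sample, dec.factor_condition)
        ):
            unfolded = np.moveaxis(vals, mode, 0).reshape(vals.shape[mode], -1)
            ref, _, _ = np.linalg.svd(unfolded, full_matrices=False)
            for l in range(factor.shape[1]):
                diff = min(
                    np.max(np.abs(factor[:, l] - ref[:, l])),
                    np.max(np.abs(factor[:, l] + ref[:, l])),
                )
                assert diff < 1e-8

    def test_full_rank_reconstruction(self, rng):
        vals = rng.normal(size=(5, 4, 3))
        dec = hosvd(_tensor(vals))
        err = np.linalg.norm(dec.reconstruct() - vals) / np.linalg.norm(vals)
        assert err < 1e-8

    def test_core_mode_slices_mutually_orthogonal(self, rng):
        dec = hosvd(_tensor(rng.normal(size=(5, 4, 3))))
        for mode in range(3):
            g = np.moveaxis(dec.core, mode, 0)
            flat = g.reshape(g.shape[0], -1)
            prod = flat @ flat.T
            np.testing.assert_allclose(prod - np.diag(np.diag(prod)), 0.0, atol=1e-8)

    def test_truncation_bounds_checked(self, rng):
        t = _tensor(rng.normal(size=(4, 3, 2)))
        dec = hosvd(t, ranks=(2, 2, 1))
        assert dec.core.shape == (2, 2, 1)
        with pytest.raises(ValueError):
            hosvd(t, ranks=(9, 1, 1))


class TestSelectAxes:
    def test_matrix_self_correlation(self, small_matrix):
        dec = pca(standardize_matrix(small_matrix))
        sel = select_axes(dec, target_sample=dec.loadings[:, 2])
        assert sel.feature_axis == 2

    def test_tensor_core_argmax_and_tie_break(self):
        from unsupfe import TensorDecomposition

        core = np.zeros((6, 2, 2))
        core[5, 0, 1] = -7.0  # unique maximal |G| at feature axis 5
        core[2, 0, 1] = 6.0
        factor_sample = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]])
        # column 1 tracks the last condition; column 0 is near-uniform
        factor_condition = np.array([[0.6, -0.1], [0.55, -0.2], [0.58, 0.9]])
        dec = TensorDecomposition(np.eye(6), factor_sample, factor_condition, core)
        sel = select_axes(
            dec,
            target_sample=np.array([1.0, 1.0, -1.0, -1.0]),
            target_condition=np.array([0.0, 0.0, 1.0]),
        )
        assert (sel.feature_axis, sel.sample_axis, sel.condition_axis) == (5, 0, 1)

        core_tied = np.zeros((4, 2, 2))
        core_tied[1, 0, 1] = 3.0
        core_tied[3, 0, 1] = -3.0
        dec_tied = TensorDecomposition(np.eye(4), factor_sample, factor_condition, core_tied)
        sel_tied = select_axes(
            dec_tied,
            target_sample=np.array([1.0, 1.0, -1.0, -1.0]),
            target_condition=np.array([0.0, 0.0, 1.0]),
        )
        assert sel_tied.feature_axis == 1  # smallest index wins the tie

    def test_explicit_mode_bounds(self, small_matrix):
        dec = pca(standardize_matrix(small_matrix))
        assert select_axes(dec, mode="explicit", explicit_indices=[1]).feature_axis == 1
        with pytest.raises(IndexError):
            select_axes(dec, mode="explicit", explicit_indices=[99])

    def test_zero_variance_target_rejected(self, small_matrix):
        dec = pca(standardize_matrix(small_matrix))
        with pytest.raises(ValueError, match="zero variance"):
            select_axes(dec, target_sample=np.ones(small_matrix.n_samples))


def test_matrix_invariants_enforced():
    with pytest.raises(ValueError):
        ExpressionMatrix(np.ones((1, 3)), ["g0"], ["a", "b", "c"])
    with pytest.raises(ValueError):
        ExpressionMatrix(np.ones((2, 2)), ["g0", "g0"], ["a", "b"])
    bad = np.ones((2, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        ExpressionMatrix(bad, ["g0", "g1"], ["a", "b"])
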