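"""Univariate FPCA, multivariate FPCA and the classical PCA baseline."""

import numpy as np
import pytest

from fdgm.decomposition import (
    UsageError,
    classical_pca,
    mfpca,
    pve,
    reconstruct,
    ufpca,
)
from fdgm.functional import (
    FunctionalDataset,
    FunctionalElement,
    trapezoid_weights,
)


def make_fd(blocks, ids=None):
    """FunctionalDataset from a list of (name, n x N values) pairs."""
    elements = []
    for name, values in blocks:
        grid = np.linspace(0, 1, values.shape[1])
        elements.append(
            FunctionalElement(name, values, grid, trapezoid_weights(grid))
        )
    n = blocks[0][1].shape[0]
    return FunctionalDataset(
        elements=elements,
        specimen_ids=ids or [f"s{i}" for i in range(n)],
    )


def weighted_pca_oracle(blocks, weights_list):
    """Quadrature-weighted PCA of row-concatenated raw data.

    Independent oracle: centre each block, scale columns by sqrt(w),
    take the SVD, return eigenvalues and (sign-unaligned) scores.
    """
    centred = [b - b.mean(axis=0) for b in blocks]
    scaled = np.hstack(
        [c * np.sqrt(w)[None, :] for c, w in zip(centred, weights_list)]
    )
    u, s, _ = np.linalg.svd(scaled, full_matrices=False)
    n = scaled.shape[0]
    return s**2 / (n - 1), u * s


class TestUFPCA:
    def test_rank_one_data_recovers_amplitudes(self, rng):
        grid = np.linspace(0, 1, 11)
        w = trapezoid_weights(grid)
        phi = np.sin(2 * np.pi * grid)
        phi = phi / np.sqrt(np.sum(w * phi**2))  # unit norm under quadrature
        a = rng.normal(size=9)
        values = np.outer(a, phi)
        res = ufpca(values, grid, w, pve_threshold=1.0)
        nonzero = res.eigenvalues[res.eigenvalues > 1e-12]
        assert nonzero.size == 1
        assert nonzero[0] == pytest.approx(np.var(a, ddof=1), rel=1e-10)
        sign = np.sign(np.sum(res.eigenfunctions[0] * phi))
        np.testing.assert_allclose(
            res.scores[:, 0], sign * (a - a.mean()), atol=1e-10
        )

    def test_eigenfunctions_orthonormal_under_quadrature(self, rng):
        grid = np.linspace(0, 1, 8)
        w = trapezoid_weights(grid)
        res = ufpca(rng.normal(size=(10, 8)), grid, w, pve_threshold=1.0)
        gram = res.eigenfunctions @ (w[:, None] * res.eigenfunctions.T)
        np.testing.assert_allclose(gram, np.eye(res.n_retained), atol=1e-8)

    def test_score_means_are_zero(self, rng):
        grid = np.linspace(0, 1, 8)
        res = ufpca(rng.normal(size=(10, 8)), grid, trapezoid_weights(grid))
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-8)

    def test_matches_dense_weighted_covariance_oracle(self, rng):
        grid = np.linspace(0, 1, 5)
        w = trapezoid_weights(grid)
        values = rng.normal(size=(8, 5))
        res = ufpca(values, grid, w, pve_threshold=1.0)
        # brute-force: explicitly assemble W^(1/2) K W^(1/2) and eigendecompose
        centred = values - values.mean(axis=0)
        cov = centred.T @ centred / 7
        sym = np.diag(np.sqrt(w)) @ cov @ np.diag(np.sqrt(w))
        oracle = np.sort(np.linalg.eigvalsh(sym))[::-1]
        k = res.eigenvalues.size
        np.testing.assert_allclose(res.eigenvalues, oracle[:k], rtol=1e-10, atol=1e-14)

    def test_pve_threshold_validated(self, rng):
        grid = np.linspace(0, 1, 5)
        with pytest.raises(UsageError):
            ufpca(rng.normal(size=(5, 5)), grid, trapezoid_weights(grid), pve_threshold=1.5)

    def test_zero_variance_element_flagged(self):
        grid = np.linspace(0, 1, 5)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = ufpca(np.ones((5, 5)), grid, trapezoid_weights(grid))
        assert res.n_retained == 1
        assert res.eigenvalues[0] == 0.0


class TestMFPCA:
    def test_duplicated_element_block_structure(self, rng):
        values = rng.normal(size=(7, 6))
        fd = make_fd([("a", values), ("b", values.copy())])
        probe = mfpca(fd, pve_threshold=1.0)
        total_j = probe.score_matrix.shape[1]
        res = mfpca(fd, pve_threshold=1.0, n_components=total_j)
        j = res.univariate[0].n_retained
        s = res.univariate[0].scores.T @ res.univariate[0].scores / 6
        # Z has the block form [[S, S], [S, S]]
        np.testing.assert_allclose(res.block_cov[:j, :j], s, atol=1e-10)
        np.testing.assert_allclose(res.block_cov[:j, j:], s, atol=1e-10)
        # nonzero eigenvalues are twice the univariate ones, the rest zero
        uni = np.sort(res.univariate[0].eigenvalues)[::-1]
        top = res.eigenvalues[:j]
        np.testing.assert_allclose(top, 2 * uni, atol=1e-10)
        np.testing.assert_allclose(res.eigenvalues[j:], 0, atol=1e-10)
        # against a direct eigendecomposition of the assembled matrix
        oracle = np.sort(np.linalg.eigvalsh(res.block_cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, oracle, atol=1e-10)

    def test_block_covariance_is_psd(self, rng):
        fd = make_fd([("a", rng.normal(size=(6, 4))), ("b", rng.normal(size=(6, 5)))])
        res = mfpca(fd, pve_threshold=1.0)
        assert np.linalg.eigvalsh(res.block_cov).min() >= -1e-10

    def test_full_retention_matches_weighted_pca_of_concatenated_data(self, rng):
        blocks = [rng.normal(size=(6, 4)), rng.normal(size=(6, 4))]
        fd = make_fd([("a", blocks[0]), ("b", blocks[1])])
        res = mfpca(fd, pve_threshold=1.0)
        eig_oracle, score_oracle = weighted_pca_oracle(
            blocks, [el.weights for el in fd.elements]
        )
        k = res.eigenvalues.size
        np.testing.assert_allclose(res.eigenvalues, eig_oracle[:k], atol=1e-8)
        for col in range(k):
            dots = res.scores[:, col] @ score_oracle[:, col]
            np.testing.assert_allclose(
                res.scores[:, col], np.sign(dots) * score_oracle[:, col], atol=1e-8
            )

    def test_karhunen_loeve_reconstruction(self, rng):
        blocks = [("a", rng.normal(size=(8, 5))), ("b", rng.normal(size=(8, 6)))]
        fd = make_fd(blocks)
        res = mfpca(fd, pve_threshold=1.0)
        for p, (_, values) in enumerate(blocks):
            centred = values - values.mean(axis=0)
            rec = reconstruct(res, p)
            rms = np.sqrt(np.mean((rec - centred) ** 2))
            assert rms < 1e-8

    def test_score_covariance_is_diagonal_eigenvalues(self, rng):
        fd = make_fd([("a", rng.normal(size=(9, 5))), ("b", rng.normal(size=(9, 5)))])
        res = mfpca(fd, pve_threshold=1.0)
        cov = res.scores.T @ res.scores / (res.scores.shape[0] - 1)
        np.testing.assert_allclose(cov, np.diag(res.eigenvalues), atol=1e-8)

    def test_bit_stable_across_runs(self, rng):
        values = rng.normal(size=(7, 5))
        fd = make_fd([("a", values), ("b", rng.normal(size=(7, 5)))])
        r1 = mfpca(fd, pve_threshold=1.0)
        r2 = mfpca(fd, pve_threshold=1.0)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        np.testing.assert_array_equal(r1.eigenvectors, r2.eigenvectors)

    def test_single_element_agrees_with_classical_pca_under_unit_weights(self, rng):
        values = rng.normal(size=(8, 6))
        grid = np.linspace(0, 1, 6)
        fd = FunctionalDataset(
            elements=[FunctionalElement("a", values, grid, np.ones(6))],
            specimen_ids=[f"s{i}" for i in range(8)],
        )
        res = mfpca(fd, pve_threshold=1.0)
        pca = classical_pca(values)
        k = min(res.eigenvalues.size, pca.eigenvalues.size)
        np.testing.assert_allclose(res.eigenvalues[:k], pca.eigenvalues[:k], atol=1e-8)

    def test_component_truncation(self, rng):
        fd = make_fd([("a", rng.normal(size=(8, 5))), ("b", rng.normal(size=(8, 5)))])
        res = mfpca(fd, pve_threshold=1.0, n_components=3)
        assert res.n_components == 3
        assert res.scores.shape == (8, 3)
        with pytest.raises(UsageError):
            mfpca(fd, pve_threshold=1.0, n_components=99)


class TestClassicalPCA:
    def test_component_count_bounded_by_n_minus_1(self, rng):
        # 10 specimens in a 16-dim space: at most 9 nonzero components
        res = classical_pca(rng.normal(size=(10, 16)))
        assert res.n_components == 9

    def test_rank_one_data(self, rng):
        base = np.zeros((6, 8))
        base[0] = rng.normal(size=8)
        res = classical_pca(base - base.mean(axis=0) + 5.0)
        assert res.n_components == 1

    def test_matches_svd_oracle(self, rng):
        matrix = rng.normal(size=(10, 8))
        res = classical_pca(matrix)
        centred = matrix - matrix.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        np.testing.assert_allclose(res.eigenvalues, (s**2 / 9)[: res.n_components],
                                   rtol=1e-10)

    def test_scores_reproduce_centred_data(self, rng):
        matrix = rng.normal(size=(9, 5))
        res = classical_pca(matrix)
        np.testing.assert_allclose(
            res.scores @ res.loadings, matrix - res.mean, atol=1e-10
        )


class TestPVE:
    def test_simple_fraction(self):
        assert pve(np.array([3.0, 1.0]), 1) == pytest.approx(0.75)

    def test_full_length_is_one(self, rng):
        vals = np.sort(rng.uniform(0.1, 1, 6))[::-1]
        assert pve(vals, 6) == pytest.approx(1.0, abs=1e-14)

    def test_matches_cumsum_oracle(self, rng):
        vals = np.sort(rng.uniform(0.1, 1, 8))[::-1]
        cum = np.cumsum(vals) / vals.sum()
        for k in range(1, 9):
            assert pve(vals, k) == pytest.approx(cum[k - 1], abs=1e-14)

    def test_all_zero_eigenvalues_error(self):
        with pytest.raises(UsageError, match="undefined"):
            pve(np.zeros(3), 1)
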