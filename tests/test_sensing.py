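"""Measurement matrices, compression, proxy back-projection and z-scoring."""

import numpy as np
import pytest

import eegcs
from eegcs.exceptions import (
    ConfigurationError,
    DegenerateFrameError,
    DimensionMismatchError,
)


def _penrose_residuals(phi: np.ndarray, pinv: np.ndarray) -> list[float]:
    """Relative residuals of the four Moore-Penrose conditions."""
    scale = np.linalg.norm(phi)
    return [
        np.linalg.norm(phi @ pinv @ phi - phi) / scale,
        np.linalg.norm(pinv @ phi @ pinv - pinv) / np.linalg.norm(pinv),
        np.linalg.norm((phi @ pinv).T - phi @ pinv) / max(np.linalg.norm(phi @ pinv), 1e-30),
        np.linalg.norm((pinv @ phi).T - pinv @ phi) / max(np.linalg.norm(pinv @ phi), 1e-30),
    ]


class TestMatrixConstruction:
    def test_gaussian_deterministic_per_seed(self):
        a = eegcs.make_gaussian_matrix(20, 50, seed=3)
        b = eegcs.make_gaussian_matrix(20, 50, seed=3)
        np.testing.assert_array_equal(a.entries, b.entries)

    def test_gaussian_column_norms_near_one(self):
        """Normal(0, 1/M) entries make E[||column||^2] = 1; the mean over 500
        columns must sit within three standard errors."""
        matrix = eegcs.make_gaussian_matrix(100, 500, seed=1)
        sq_norms = np.sum(matrix.entries**2, axis=0)
        se = sq_norms.std(ddof=1) / np.sqrt(sq_norms.size)
        assert abs(sq_norms.mean() - 1.0) <= 3 * se

    @pytest.mark.parametrize("M,N", [(500, 500), (600, 500), (0, 10)])
    def test_non_compressive_shapes_rejected(self, M, N):
        with pytest.raises(ConfigurationError):
            eegcs.make_gaussian_matrix(M, N, seed=0)

    def test_sparse_binary_column_counts(self):
        matrix = eegcs.make_sparse_binary_matrix(30, 90, ones_per_column=4, seed=2)
        assert set(np.unique(matrix.entries)) <= {0.0, 1.0}
        np.testing.assert_array_equal(matrix.entries.sum(axis=0), np.full(90, 4.0))
        assert matrix.entries.sum() == 90 * 4

    def test_sparse_binary_all_ones_at_degenerate_bound(self):
        matrix = eegcs.make_sparse_binary_matrix(5, 8, ones_per_column=5, seed=0)
        np.testing.assert_array_equal(matrix.entries, np.ones((5, 8)))

    def test_sparse_binary_deterministic_and_bounds(self):
        a = eegcs.make_sparse_binary_matrix(30, 90, seed=2)
        b = eegcs.make_sparse_binary_matrix(30, 90, seed=2)
        np.testing.assert_array_equal(a.entries, b.entries)
        with pytest.raises(ConfigurationError):
            eegcs.make_sparse_binary_matrix(10, 20, ones_per_column=11, seed=0)


class TestCompress:
    def test_hand_matvec(self):
        matrix = eegcs.MeasurementMatrix(
            entries=np.array([[1.0, 0, 1, 0], [0, 1, 0, 1]]), kind="sparse_binary"
        )
        y = eegcs.compress(matrix, np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(y.values, [4.0, 6.0])

    def test_zero_frame_gives_zero_measurement(self):
        matrix = eegcs.make_gaussian_matrix(10, 30, seed=0)
        y = eegcs.compress(matrix, np.zeros(30))
        np.testing.assert_array_equal(y.values, np.zeros(10))

    def test_sparse_binary_equals_row_sum_oracle(self, rng):
        """y must equal per-row sums of the selected x entries, checked
        against an explicit double loop."""
        matrix = eegcs.make_sparse_binary_matrix(12, 40, seed=5)
        x = rng.normal(size=40)
        y = eegcs.compress(matrix, x)
        expected = np.array(
            [
                sum(x[j] for j in range(40) if matrix.entries[i, j] == 1.0)
                for i in range(12)
            ]
        )
        np.testing.assert_allclose(y.values, expected, rtol=1e-12)

    def test_linearity(self, rng):
        matrix = eegcs.make_gaussian_matrix(15, 40, seed=1)
        x1, x2 = rng.normal(size=40), rng.normal(size=40)
        lhs = eegcs.compress(matrix, 2.5 * x1 - 1.5 * x2).values
        rhs = 2.5 * eegcs.compress(matrix, x1).values - 1.5 * eegcs.compress(matrix, x2).values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_length_mismatch_rejected(self):
        matrix = eegcs.make_gaussian_matrix(10, 30, seed=0)
        with pytest.raises(DimensionMismatchError):
            eegcs.compress(matrix, np.zeros(29))


class TestPseudoInverse:
    def test_identity_matrix(self):
        matrix = eegcs.MeasurementMatrix(entries=np.eye(6), kind="gaussian")
        np.testing.assert_allclose(eegcs.pseudo_inverse(matrix), np.eye(6), atol=1e-12)

    def test_row_orthonormal_closed_form(self):
        """For a matrix with orthonormal rows the pseudo-inverse is the
        transpose."""
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(9, 5)))
        matrix = eegcs.MeasurementMatrix(entries=q.T, kind="gaussian")
        np.testing.assert_allclose(eegcs.pseudo_inverse(matrix), q, atol=1e-10)

    @pytest.mark.parametrize("kind", ["gaussian", "sparse_binary"])
    def test_penrose_identities(self, kind):
        if kind == "gaussian":
            matrix = eegcs.make_gaussian_matrix(5, 9, seed=3)
        else:
            matrix = eegcs.make_sparse_binary_matrix(5, 9, ones_per_column=2, seed=3)
        residuals = _penrose_residuals(matrix.entries, eegcs.pseudo_inverse(matrix))
        assert max(residuals) <= 1e-8


class TestProxy:
    def test_zero_measurement_gives_zero_proxy(self):
        matrix = eegcs.make_gaussian_matrix(8, 20, seed=0)
        y = eegcs.compress(matrix, np.zeros(20))
        np.testing.assert_array_equal(eegcs.proxy(matrix, y).values, np.zeros(20))

    def test_row_space_vectors_recovered_exactly(self, rng):
        """If x lies in the row space of Phi the proxy equals x."""
        matrix = eegcs.make_gaussian_matrix(8, 20, seed=4)
        x = matrix.entries.T @ rng.normal(size=8)
        x_tilde = eegcs.proxy(matrix, eegcs.compress(matrix, x))
        np.testing.assert_allclose(x_tilde.values, x, atol=1e-8)

    def test_proxy_is_row_space_projection(self, rng):
        """The proxy must equal the orthogonal projection of x onto the row
        space, computed through the independent projector
        Phi^T (Phi Phi^T)^{-1} Phi."""
        matrix = eegcs.make_gaussian_matrix(8, 20, seed=4)
        phi = matrix.entries
        projector = phi.T @ np.linalg.solve(phi @ phi.T, phi)
        x = rng.normal(size=20)
        x_tilde = eegcs.proxy(matrix, eegcs.compress(matrix, x))
        np.testing.assert_allclose(x_tilde.values, projector @ x, atol=1e-8)

    def test_proxy_compress_idempotent(self, rng):
        matrix = eegcs.make_sparse_binary_matrix(10, 30, seed=6)
        x = rng.normal(size=30)
        once = eegcs.proxy(matrix, eegcs.compress(matrix, x)).values
        twice = eegcs.proxy(matrix, eegcs.compress(matrix, once)).values
        np.testing.assert_allclose(once, twice, atol=1e-8)

    def test_foreign_measurement_rejected(self):
        m1 = eegcs.make_gaussian_matrix(8, 20, seed=0)
        m2 = eegcs.make_gaussian_matrix(9, 20, seed=0)
        y = eegcs.compress(m1, np.ones(20))
        with pytest.raises(DimensionMismatchError):
            eegcs.proxy(m2, y)


class TestZscore:
    def test_hand_example(self):
        result = eegcs.zscore(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            result.values, [-1.224744871391589, 0.0, 1.224744871391589], rtol=1e-12
        )
        assert result.mu == pytest.approx(2.0)
        assert result.sigma == pytest.approx(0.816496580927726, rel=1e-12)

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        result = eegcs.zscore(x)
        np.testing.assert_allclose(result.values, x, atol=1e-9)
        assert abs(result.mu) < 1e-9
        assert result.sigma == pytest.approx(1.0, abs=1e-9)

    def test_output_moments(self, rng):
        for _ in range(5):
            result = eegcs.zscore(rng.normal(loc=3.0, scale=7.0, size=123))
            assert abs(result.values.mean()) <= 1e-9
            assert abs(result.values.std() - 1.0) <= 1e-9

    def test_constant_frame_raises_degenerate_error(self):
        with pytest.raises(DegenerateFrameError):
            eegcs.zscore(np.array([5.0, 5.0, 5.0]))


class TestCompressionRatio:
    @pytest.mark.parametrize(
        "M,N,expected", [(450, 500, 0.90), (50, 500, 0.10), (250, 500, 0.5), (7, 7, 1.0)]
    )
    def test_ratio_values(self, M, N, expected):
        assert eegcs.compression_ratio(M, N) == pytest.approx(expected, rel=1e-15)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ConfigurationError):
            eegcs.compression_ratio(501, 500)
        with pytest.raises(ConfigurationError):
            eegcs.compression_ratio(0, 500)
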