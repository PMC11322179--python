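"""Greedy sparse recovery, the exhaustive l0 oracle and RIP estimation."""

import numpy as np
import pytest

import eegcs
from eegcs.baselines import _EXHAUSTIVE_LIMIT
from eegcs.exceptions import ConfigurationError


class TestBases:
    def test_dct_basis_is_orthonormal(self):
        psi = eegcs.dct_basis(32)
        np.testing.assert_allclose(psi.matrix.T @ psi.matrix, np.eye(32), atol=1e-10)

    def test_matched_cosine_concentrates_on_one_coefficient(self):
        """A frame equal to one DCT-II basis vector must put essentially all
        of its coefficient energy on a single index."""
        N = 64
        psi = eegcs.dct_basis(N)
        n = np.arange(N)
        k = 5
        x = np.cos(np.pi * (n + 0.5) * k / N)
        s = psi.analyze(x)
        assert s[k] ** 2 / np.sum(s**2) >= 0.999

    def test_identity_basis_is_transparent(self, rng):
        psi = eegcs.identity_basis(16)
        x = rng.normal(size=16)
        np.testing.assert_array_equal(psi.analyze(x), x)
        np.testing.assert_array_equal(psi.synthesize(x), x)


class TestOmp:
    def test_zero_measurement_returns_zero_solution(self):
        theta = np.random.default_rng(0).normal(size=(8, 12))
        sol = eegcs.omp(theta, np.zeros(8), K=3)
        assert sol.iterations == 0
        assert sol.support == ()
        np.testing.assert_array_equal(sol.coefficients, np.zeros(12))

    def test_orthonormal_dictionary_closed_form(self):
        """With orthonormal columns and y = 3 * column 7, one iteration must
        select atom 7 with coefficient 3 and zero residual."""
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        sol = eegcs.omp(q, 3.0 * q[:, 7], K=3)
        assert sol.support == (7,)
        assert sol.coefficients[7] == pytest.approx(3.0, rel=1e-10)
        assert sol.residual_norm <= 1e-10
        assert sol.iterations == 1

    def test_residuals_non_increasing(self, rng):
        theta = rng.normal(size=(10, 25))
        y = rng.normal(size=10)
        sol = eegcs.omp(theta, y, K=6, tol=0.0)
        history = (np.linalg.norm(y),) + sol.residual_history
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_support_grows_one_atom_per_iteration(self, rng):
        theta = rng.normal(size=(10, 25))
        sol = eegcs.omp(theta, rng.normal(size=10), K=5, tol=0.0)
        assert len(sol.support) == sol.iterations == 5

    def test_rejects_bad_inputs(self, rng):
        theta = rng.normal(size=(6, 10))
        with pytest.raises(ConfigurationError):
            eegcs.omp(theta, np.zeros(6), K=7)  # K > M
        theta[:, 4] = 0.0
        with pytest.raises(ConfigurationError):
            eegcs.omp(theta, np.ones(6), K=2)  # zero column


class TestCosamp:
    def test_zero_measurement_returns_zero_solution(self, rng):
        theta = rng.normal(size=(8, 12))
        sol = eegcs.cosamp(theta, np.zeros(8), K=3)
        assert sol.residual_norm == 0.0
        np.testing.assert_array_equal(sol.coefficients, np.zeros(12))

    def test_recovers_planted_sparse_vector(self):
        """M >= 4K well-conditioned Gaussian dictionary: an exactly K-sparse
        measurement must be recovered to numerical precision."""
        rng = np.random.default_rng(3)
        M, N, K = 16, 32, 3
        theta = rng.normal(size=(M, N)) / np.sqrt(M)
        support = [4, 11, 25]
        s_true = np.zeros(N)
        s_true[support] = [2.0, -1.5, 3.0]
        y = theta @ s_true
        sol = eegcs.cosamp(theta, y, K)
        assert sol.residual_norm <= 1e-6 * np.linalg.norm(y)
        assert sol.support == tuple(support)

    def test_support_never_exceeds_k(self, rng):
        theta = rng.normal(size=(12, 30))
        for _ in range(5):
            sol = eegcs.cosamp(theta, rng.normal(size=12), K=4)
            assert len(sol.support) <= 4

    def test_k_larger_than_m_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            eegcs.cosamp(rng.normal(size=(6, 10)), np.ones(6), K=7)


class TestL0Oracle:
    def test_recovers_planted_support_noiselessly(self):
        rng = np.random.default_rng(5)
        theta = rng.normal(size=(8, 12))
        s_true = np.zeros(12)
        s_true[[2, 9]] = [1.0, -2.0]
        sol = eegcs.l0_oracle(theta, theta @ s_true, K=2)
        assert sol.support == (2, 9)
        assert sol.residual_norm <= 1e-10

    def test_k_zero_returns_zero_solution(self, rng):
        theta = rng.normal(size=(6, 9))
        y = rng.normal(size=6)
        sol = eegcs.l0_oracle(theta, y, K=0)
        np.testing.assert_array_equal(sol.coefficients, np.zeros(9))
        assert sol.residual_norm == pytest.approx(np.linalg.norm(y))

    def test_dominates_omp_on_tiny_instances(self):
        """Optimality ordering on every instance: l0 residual <= OMP residual
        <= ||y||."""
        rng = np.random.default_rng(6)
        for trial in range(20):
            theta = rng.normal(size=(8, 12))
            y = rng.normal(size=8)
            oracle = eegcs.l0_oracle(theta, y, K=2)
            greedy = eegcs.omp(theta, y, K=2, tol=0.0)
            assert oracle.residual_norm <= greedy.residual_norm + 1e-9
            assert greedy.residual_norm <= np.linalg.norm(y) + 1e-12

    def test_too_large_instance_rejected(self, rng):
        theta = rng.normal(size=(10, 100))
        with pytest.raises(ConfigurationError):
            eegcs.l0_oracle(theta, np.ones(10), K=4)  # C(100,4) >> budget


class TestReconstructClassical:
    def test_zero_measurement_gives_zero_frame(self):
        matrix = eegcs.make_gaussian_matrix(10, 24, seed=0)
        frame = eegcs.reconstruct_classical(
            matrix, eegcs.identity_basis(24), np.zeros(10), algo="omp", K=3
        )
        np.testing.assert_allclose(frame.values, np.zeros(24), atol=1e-12)

    def test_monte_carlo_exact_recovery_with_identity_basis(self):
        """Exactly K-sparse frames under a generous Gaussian matrix must be
        recovered in >= 95% of seeded trials."""
        successes = 0
        n_trials = 50
        M, N, K = 32, 64, 4
        for seed in range(n_trials):
            rng = np.random.default_rng(1000 + seed)
            matrix = eegcs.make_gaussian_matrix(M, N, seed=seed)
            x = np.zeros(N)
            support = rng.choice(N, size=K, replace=False)
            x[support] = rng.normal(size=K) + np.sign(rng.normal(size=K))
            y = matrix.entries @ x
            frame = eegcs.reconstruct_classical(
                matrix, eegcs.identity_basis(N), y, algo="omp", K=K
            )
            if np.linalg.norm(frame.values - x) <= 1e-6 * np.linalg.norm(x):
                successes += 1
        assert successes / n_trials >= 0.95

    def test_omp_residual_non_increasing_in_k(self, rng):
        matrix = eegcs.make_gaussian_matrix(16, 40, seed=2)
        basis = eegcs.dct_basis(40)
        x = rng.normal(size=40)
        y = matrix.entries @ x
        prev = np.inf
        for K in (1, 2, 4, 8):
            frame = eegcs.reconstruct_classical(matrix, basis, y, algo="omp", K=K)
            residual = np.linalg.norm(y - matrix.entries @ frame.values)
            assert residual <= prev + 1e-9
            prev = residual


class TestEmpiricalRip:
    def test_orthonormal_columns_give_zero_delta(self):
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        matrix = eegcs.MeasurementMatrix(entries=q, kind="gaussian")
        estimate = eegcs.empirical_rip(matrix, K=2)
        assert estimate.exhaustive
        assert estimate.delta_hat == pytest.approx(0.0, abs=1e-10)

    def test_k1_closed_form_from_column_norms(self):
        """delta_1 = max_j |  ||phi_j||^2 - 1 |."""
        entries = np.diag([1.0, 0.5, 2.0])[:, :3]
        matrix = eegcs.MeasurementMatrix(entries=entries, kind="gaussian")
        estimate = eegcs.empirical_rip(matrix, K=1)
        assert estimate.delta_hat == pytest.approx(3.0)  # |2^2 - 1| = 3

    def test_sampled_never_exceeds_exhaustive(self):
        matrix = eegcs.make_gaussian_matrix(8, 14, seed=9)
        exhaustive = eegcs.empirical_rip(matrix, K=2)
        sampled = eegcs.empirical_rip(matrix, K=2, n_samples=30, seed=1)
        assert not sampled.exhaustive
        assert sampled.delta_hat <= exhaustive.delta_hat + 1e-12

    def test_exhaustive_budget_enforced(self):
        matrix = eegcs.make_gaussian_matrix(10, 100, seed=0)
        with pytest.raises(ConfigurationError):
            eegcs.empirical_rip(matrix, K=5)
        assert eegcs.empirical_rip(matrix, K=5, n_samples=10).delta_hat >= 0.0
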