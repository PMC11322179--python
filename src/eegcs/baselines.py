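"""Classical iterative compressed-sensing recovery: OMP, CoSaMP and oracles.

Under the sparse-synthesis model x = Psi s with an orthonormal basis Psi and
a K-sparse coefficient vector s, the measurement y = Phi x = Theta s with
dictionary Theta = Phi Psi.  Recovery seeks the sparsest s consistent with
y; the exact l0 problem is combinatorial, so greedy pursuits (OMP, CoSaMP)
approximate it.  A brute-force l0 oracle and an empirical restricted-isometry
estimate are provided for small instances, serving as ground truth in tests
and experiments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import scipy.fft

from .exceptions import ConfigurationError, DimensionMismatchError
from .model import ReconstructedFrame
from .sensing import MeasurementMatrix

__all__ = [
    "SparsifyingBasis",
    "SparseSolution",
    "RipEstimate",
    "dct_basis",
    "identity_basis",
    "omp",
    "cosamp",
    "l0_oracle",
    "reconstruct_classical",
    "empirical_rip",
]

_EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class SparsifyingBasis:
    """An orthonormal N x N basis Psi such that x = Psi s."""

    matrix: np.ndarray
    kind: str

    @property
    def N(self) -> int:
        return self.matrix.shape[0]

    def analyze(self, x: np.ndarray) -> np.ndarray:
        """Coefficients s = Psi^T x."""
        return self.matrix.T @ x

    def synthesize(self, s: np.ndarray) -> np.ndarray:
        """Signal x = Psi s."""
        return self.matrix @ s


@dataclass(frozen=True)
class SparseSolution:
    """A sparse coefficient estimate with its support and fit diagnostics."""

    coefficients: np.ndarray
    support: tuple[int, ...]
    K: int
    residual_norm: float
    iterations: int
    residual_history: tuple[float, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "support", tuple(sorted(self.support)))


@dataclass(frozen=True)
class RipEstimate:
    """Empirical restricted-isometry constant estimate for sparsity K.

    ``delta_hat`` is the worst deviation of any inspected M x K column
    submatrix from an isometry.  When ``exhaustive`` is False only a sample
    of supports was inspected, so the estimate lower-bounds the true
    constant.
    """

    delta_hat: float
    K: int
    exhaustive: bool


def dct_basis(N: int) -> SparsifyingBasis:
    """Orthonormal DCT-II synthesis basis — the customary sparse transform
    for smooth biosignal frames."""
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    # columns are the DCT-II basis vectors; analyze() is then the DCT itself
    psi = scipy.fft.idct(np.eye(N), axis=0, norm="ortho")
    return SparsifyingBasis(matrix=psi, kind="dct")


def identity_basis(N: int) -> SparsifyingBasis:
    """Identity basis for exactly-sparse synthetic experiments (s = x)."""
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    return SparsifyingBasis(matrix=np.eye(N), kind="identity")


def _lstsq_on_support(theta: np.ndarray, y: np.ndarray, support) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit restricted to the given columns; returns (s, residual)."""
    support = list(support)
    s = np.zeros(theta.shape[1])
    if not support:
        return s, y.copy()
    coef, *_ = np.linalg.lstsq(theta[:, support], y, rcond=None)
    s[support] = coef
    return s, y - theta[:, support] @ coef


def omp(theta: np.ndarray, y: np.ndarray, K: int, tol: float = 1e-10) -> SparseSolution:
    """Orthogonal matching pursuit.

    Per iteration the column most correlated with the current residual joins
    the support (lowest index wins exact ties) and the coefficients are
    re-fitted by least squares on the accumulated support.  Stops after K
    atoms or once the residual norm drops to ``tol * ||y||``.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    M, N = theta.shape
    if y.shape != (M,):
        raise DimensionMismatchError(f"y must have length {M}")
    if not (0 <= K <= M):
        raise ConfigurationError(f"need 0 <= K <= M={M}, got K={K}")
    col_norms = np.linalg.norm(theta, axis=0)
    if np.any(col_norms == 0):
        raise ConfigurationError("dictionary contains a zero column")
    y_norm = float(np.linalg.norm(y))
    support: list[int] = []
    s = np.zeros(N)
    residual = y.copy()
    history: list[float] = []
    iterations = 0
    while len(support) < K and np.linalg.norm(residual) > tol * y_norm:
        correlations = np.abs(theta.T @ residual) / col_norms
        correlations[support] = -np.inf
        atom = int(np.argmax(correlations))  # argmax takes the lowest index on ties
        support.append(atom)
        s, residual = _lstsq_on_support(theta, y, support)
        history.append(float(np.linalg.norm(residual)))
        iterations += 1
    return SparseSolution(
        coefficients=s,
        support=tuple(support),
        K=K,
        residual_norm=float(np.linalg.norm(residual)),
        iterations=iterations,
        residual_history=tuple(history),
    )


def cosamp(
    theta: np.ndarray, y: np.ndarray, K: int, max_iter: int = 50, tol: float = 1e-6
) -> SparseSolution:
    """Compressive sampling matching pursuit.

    Each iteration merges the 2K largest entries of the correlation proxy
    ``Theta^T residual`` into the current support, solves least squares on
    the merged support, prunes back to the K largest coefficients and updates
    the residual.  Stops on ``max_iter`` or when the relative residual change
    falls below ``tol``; the best iterate by residual norm is returned.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    M, N = theta.shape
    if y.shape != (M,):
        raise DimensionMismatchError(f"y must have length {M}")
    if not (1 <= K <= M):
        raise ConfigurationError(f"need 1 <= K <= M={M}, got K={K}")
    y_norm = float(np.linalg.norm(y))
    if y_norm == 0.0:
        return SparseSolution(
            coefficients=np.zeros(N), support=(), K=K, residual_norm=0.0, iterations=0
        )
    support: np.ndarray = np.empty(0, dtype=int)
    s = np.zeros(N)
    residual = y.copy()
    best = (np.inf, s, support)
    prev_norm = np.inf
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        proxy_corr = np.abs(theta.T @ residual)
        candidates = np.argsort(-proxy_corr, kind="stable")[: 2 * K]
        merged = np.union1d(support, candidates)
        s_merged, _ = _lstsq_on_support(theta, y, merged.tolist())
        top = merged[np.argsort(-np.abs(s_merged[merged]), kind="stable")[:K]]
        support = np.sort(top)
        s, residual = _lstsq_on_support(theta, y, support.tolist())
        r_norm = float(np.linalg.norm(residual))
        history.append(r_norm)
        if r_norm < best[0]:
            best = (r_norm, s.copy(), support.copy())
        if abs(prev_norm - r_norm) < tol * y_norm or r_norm <= tol * y_norm:
            break
        prev_norm = r_norm
    r_norm, s, support = best
    return SparseSolution(
        coefficients=s,
        support=tuple(int(i) for i in support),
        K=K,
        residual_norm=r_norm,
        iterations=it,
        residual_history=tuple(history),
    )


def l0_oracle(theta: np.ndarray, y: np.ndarray, K: int) -> SparseSolution:
    """Exhaustive minimum-residual solver over all supports of size <= K.

    The l0 problem is combinatorial, so this runs only when C(N, K) stays
    within a small enumeration budget; it is the ground-truth reference the
    greedy pursuits are compared against.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    M, N = theta.shape
    if y.shape != (M,):
        raise DimensionMismatchError(f"y must have length {M}")
    if K < 0:
        raise ConfigurationError("K must be >= 0")
    if comb(N, min(K, N)) > _EXHAUSTIVE_LIMIT:
        raise ConfigurationError(
            f"C({N},{K}) = {comb(N, min(K, N))} exceeds the enumeration budget "
            f"{_EXHAUSTIVE_LIMIT}"
        )
    best_s = np.zeros(N)
    best_support: tuple[int, ...] = ()
    best_norm = float(np.linalg.norm(y))
    n_checked = 0
    for size in range(1, min(K, N) + 1):
        for support in itertools.combinations(range(N), size):
            s, residual = _lstsq_on_support(theta, y, list(support))
            n_checked += 1
            r_norm = float(np.linalg.norm(residual))
            if r_norm < best_norm - 1e-12:
                best_norm = r_norm
                best_s = s
                best_support = support
    return SparseSolution(
        coefficients=best_s,
        support=best_support,
        K=K,
        residual_norm=best_norm,
        iterations=n_checked,
    )


def reconstruct_classical(
    matrix: MeasurementMatrix,
    basis: SparsifyingBasis,
    y: np.ndarray,
    algo: str = "omp",
    K: int | None = None,
    **solver_kwargs,
) -> ReconstructedFrame:
    """Recover a frame via sparse coding: solve for s_hat in Theta = Phi Psi,
    then synthesize x_hat = Psi s_hat.

    The sparsity level defaults to K = round(0.1 * N), reported via the
    returned solver diagnostics when needed.
    """
    if basis.N != matrix.N:
        raise DimensionMismatchError(f"basis N {basis.N} != matrix N {matrix.N}")
    if algo not in ("omp", "cosamp"):
        raise ConfigurationError(f"algo must be 'omp' or 'cosamp', got {algo!r}")
    K = K if K is not None else max(1, round(0.1 * matrix.N))
    theta = matrix.entries @ basis.matrix
    solver = omp if algo == "omp" else cosamp
    solution = solver(theta, np.asarray(y, dtype=float), K, **solver_kwargs)
    return ReconstructedFrame(values=basis.synthesize(solution.coefficients))


def empirical_rip(
    matrix: MeasurementMatrix,
    K: int,
    n_samples: int | None = None,
    seed: int = 0,
) -> RipEstimate:
    """Empirical restricted-isometry constant of Phi at sparsity K.

    For each inspected support S the extreme singular values of the M x K
    submatrix Phi_S give the local deviation max(|sigma_max^2 - 1|,
    |1 - sigma_min^2|); the estimate is the maximum over supports.  All
    C(N, K) supports are enumerated when that count is within the budget,
    otherwise ``n_samples`` uniformly drawn supports are inspected and the
    result only lower-bounds the true constant.
    """
    if K < 1 or K > matrix.N:
        raise ConfigurationError(f"need 1 <= K <= N={matrix.N}")
    N = matrix.N
    total = comb(N, K)
    exhaustive = n_samples is None
    if exhaustive and total > _EXHAUSTIVE_LIMIT:
        raise ConfigurationError(
            f"C({N},{K}) = {total} exceeds the enumeration budget; pass n_samples"
        )
    if exhaustive:
        supports = itertools.combinations(range(N), K)
    else:
        rng = np.random.default_rng(seed)
        supports = (
            tuple(rng.choice(N, size=K, replace=False)) for _ in range(n_samples)
        )
    delta = 0.0
    for support in supports:
        sub = matrix.entries[:, list(support)]
        svals = np.linalg.svd(sub, compute_uv=False)
        delta = max(delta, abs(svals[0] ** 2 - 1.0), abs(1.0 - svals[-1] ** 2))
    return RipEstimate(delta_hat=float(delta), K=K, exhaustive=exhaustive)
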