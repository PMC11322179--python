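"""Compressed acquisition and proxy preprocessing.

A frame ``x`` of length ``N`` is compressed to ``y = Phi x`` with an
``M x N`` measurement matrix (``M < N``).  The non-iterative reconstruction
pipeline then back-projects the measurement with the Moore-Penrose
pseudo-inverse, ``x_tilde = pinv(Phi) y`` (the *proxy* signal, same length as
``x``), and z-scores it per frame before it is handed to the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DegenerateFrameError, DimensionMismatchError

__all__ = [
    "SignalFrame",
    "CompressedFrame",
    "ProxyFrame",
    "NormalizedFrame",
    "MeasurementMatrix",
    "make_gaussian_matrix",
    "make_sparse_binary_matrix",
    "compress",
    "pseudo_inverse",
    "proxy",
    "zscore",
    "compression_ratio",
]

_SIGMA_FLOOR = 1e-8


def _as_vector(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DimensionMismatchError(f"{name} must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class SignalFrame:
    """One length-N real signal frame, the unit the whole pipeline operates on."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", _as_vector(self.values, "frame"))

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CompressedFrame:
    """A length-M measurement vector y together with the matrix that produced it."""

    values: np.ndarray
    matrix: "MeasurementMatrix"

    def __post_init__(self):
        object.__setattr__(self, "values", _as_vector(self.values, "measurement"))
        if self.values.shape[0] != self.matrix.M:
            raise DimensionMismatchError(
                f"measurement length {self.values.shape[0]} != matrix M {self.matrix.M}"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ProxyFrame:
    """The pseudo-inverse back-projection x_tilde = pinv(Phi) y, length N."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", _as_vector(self.values, "proxy"))

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NormalizedFrame:
    """A z-scored proxy frame r with its original moments (mu, sigma) attached."""

    values: np.ndarray
    mu: float
    sigma: float

    def __post_init__(self):
        object.__setattr__(self, "values", _as_vector(self.values, "normalized frame"))
        if self.sigma <= 0:
            raise DegenerateFrameError(f"sigma must be positive, got {self.sigma}")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class MeasurementMatrix:
    """An M x N sensing operator Phi with a lazily cached pseudo-inverse.

    ``kind`` is ``"gaussian"`` (i.i.d. Normal(0, 1/M) entries) or
    ``"sparse_binary"`` (0/1 entries, a fixed number of ones per column).
    Square matrices are tolerated for lossless test cases; the factory
    functions enforce strict compression M < N.
    """

    entries: np.ndarray
    kind: str
    seed: int | None = None
    ones_per_column: int | None = None
    _pinv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2:
            raise DimensionMismatchError("matrix entries must be 2-D")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("matrix entries must be finite")
        M, N = self.entries.shape
        if M > N:
            raise ConfigurationError(f"M={M} > N={N}: tall matrices are not sensing operators")

    @property
    def M(self) -> int:
        return self.entries.shape[0]

    @property
    def N(self) -> int:
        return self.entries.shape[1]

    @property
    def pinv(self) -> np.ndarray:
        """The N x M Moore-Penrose pseudo-inverse, computed on first access.

        Uses an SVD with cutoff ``rcond = max(M, N) * eps`` relative to the
        largest singular value, which stays stable for rank-deficient
        sparse-binary draws.
        """
        if self._pinv is None:
            rcond = max(self.entries.shape) * np.finfo(float).eps
            self._pinv = np.linalg.pinv(self.entries, rcond=rcond)
        return self._pinv


def make_gaussian_matrix(M: int, N: int, seed: int = 0) -> MeasurementMatrix:
    """Draw a dense Gaussian sensing matrix with i.i.d. Normal(0, 1/M) entries.

    The 1/M variance makes the expected squared column norm 1, the customary
    scaling under which restricted-isometry guarantees are stated.
    """
    if not (0 < M < N):
        raise ConfigurationError(f"need 0 < M < N for compression, got M={M}, N={N}")
    rng = np.random.default_rng(seed)
    entries = rng.normal(0.0, 1.0 / np.sqrt(M), size=(M, N))
    return MeasurementMatrix(entries=entries, kind="gaussian", seed=seed)


def make_sparse_binary_matrix(
    M: int, N: int, ones_per_column: int = 4, seed: int = 0
) -> MeasurementMatrix:
    """Draw a sparse binary sensing matrix.

    Each column carries exactly ``ones_per_column`` ones at distinct,
    uniformly drawn rows; every other entry is 0.  Fixing the count per
    column guarantees every input sample contributes to some measurement.
    """
    if not (0 < M < N):
        raise ConfigurationError(f"need 0 < M < N for compression, got M={M}, N={N}")
    if not (0 < ones_per_column <= M):
        raise ConfigurationError(
            f"ones_per_column must lie in [1, M={M}], got {ones_per_column}"
        )
    rng = np.random.default_rng(seed)
    entries = np.zeros((M, N))
    for j in range(N):
        rows = rng.choice(M, size=ones_per_column, replace=False)
        entries[rows, j] = 1.0
    return MeasurementMatrix(
        entries=entries, kind="sparse_binary", seed=seed, ones_per_column=ones_per_column
    )


def compress(matrix: MeasurementMatrix, frame: SignalFrame | np.ndarray) -> CompressedFrame:
    """Acquire a frame: y = Phi x (exact matrix-vector product)."""
    x = frame.values if isinstance(frame, SignalFrame) else _as_vector(frame, "frame")
    if x.shape[0] != matrix.N:
        raise DimensionMismatchError(f"frame length {x.shape[0]} != matrix N {matrix.N}")
    return CompressedFrame(values=matrix.entries @ x, matrix=matrix)


def pseudo_inverse(matrix: MeasurementMatrix) -> np.ndarray:
    """Return (and cache) the N x M Moore-Penrose pseudo-inverse of Phi."""
    return matrix.pinv


def proxy(matrix: MeasurementMatrix, compressed: CompressedFrame) -> ProxyFrame:
    """Back-project a measurement to signal space: x_tilde = pinv(Phi) y.

    The result has the original signal dimension N and equals the orthogonal
    projection of the original frame onto the row space of Phi.
    """
    if compressed.matrix is not matrix:
        if compressed.matrix.entries.shape != matrix.entries.shape or not np.array_equal(
            compressed.matrix.entries, matrix.entries
        ):
            raise DimensionMismatchError("compressed frame does not belong to this matrix")
    return ProxyFrame(values=matrix.pinv @ compressed.values)


def zscore(proxy_frame: ProxyFrame | np.ndarray) -> NormalizedFrame:
    """Standardize a proxy frame to mean 0 and population standard deviation 1.

    The per-frame moments are stored on the result.  Constant frames cannot
    be standardized and raise :class:`DegenerateFrameError`.
    """
    x = proxy_frame.values if isinstance(proxy_frame, ProxyFrame) else _as_vector(
        proxy_frame, "proxy"
    )
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # population (divide-by-N) standard deviation
    if sigma <= _SIGMA_FLOOR:
        raise DegenerateFrameError(
            f"frame is (numerically) constant: population std {sigma:.3e} <= {_SIGMA_FLOOR}"
        )
    return NormalizedFrame(values=(x - mu) / sigma, mu=mu, sigma=sigma)


def compression_ratio(M: int, N: int) -> float:
    """CR = M / N, the fraction of samples retained by the acquisition."""
    if not (0 < M <= N):
        raise ConfigurationError(f"need 0 < M <= N, got M={M}, N={N}")
    return M / N
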