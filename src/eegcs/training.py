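"""Training the reconstruction network on (normalized proxy, original frame) pairs.

The supervision signal is the raw frame itself: for every frame x the
acquisition y = Phi x is back-projected and z-scored to r, and the network is
fitted to minimize the batch loss

    L = (1/l) * sum_i || x_hat_i - x_i ||_2^2

(the mean over frames of squared Euclidean norms, i.e. N times the
per-element MSE) with Adam on shuffled mini-batches.

Two interfaces are provided.  The functional one (`make_pairs`, `mse_loss`,
`train`) mirrors the pipeline steps directly.  The object interface follows
the estimator/results convention of statistical modelling packages:
``CSResNetModel`` holds the data and architecture, ``fit()`` runs the
optimization and returns a ``CSResNetResults`` carrying the trained network,
the loss history, diagnostics, ``summary()``, ``reconstruct()`` and plotting
helpers.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DimensionMismatchError, TrainingDivergedError
from .model import CSResNet, ModelConfig, default_model_config
from .sensing import MeasurementMatrix
from .synthetic import FrameSet

__all__ = [
    "TrainingPairs",
    "HyperParams",
    "TrainingHistory",
    "make_pairs",
    "mse_loss",
    "train",
    "CSResNetModel",
    "CSResNetResults",
]

_SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class TrainingPairs:
    """Aligned (r_i, x_i) examples produced from one measurement matrix."""

    inputs: np.ndarray        # (n, N) normalized proxies r
    targets: np.ndarray       # (n, N) raw original frames x
    matrix: MeasurementMatrix
    split: str = "train"
    n_skipped: int = 0
    mus: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigmas: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.inputs.shape != self.targets.shape:
            raise DimensionMismatchError(
                f"inputs {self.inputs.shape} vs targets {self.targets.shape}"
            )

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass(frozen=True)
class HyperParams:
    """Optimizer settings: Adam, learning rate 0.001, batch size 64."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    early_stop_patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be nonnegative")
        if self.batch_size < 1 or self.epochs < 1 or self.early_stop_patience < 1:
            raise ConfigurationError("batch_size, epochs and patience must be positive")
        if not (0.0 <= self.val_fraction < 0.5):
            raise ConfigurationError("val_fraction must lie in [0, 0.5)")


@dataclass
class TrainingHistory:
    """Per-epoch train/validation losses and the best validation epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        """Per-epoch losses as a DataFrame (epoch, train_loss, val_loss)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_pairs(
    frames: FrameSet,
    matrix: MeasurementMatrix,
    split: str = "train",
    standardize_targets: bool = False,
) -> TrainingPairs:
    """Compress, back-project and z-score every frame, pairing r with raw x.

    Labels are the raw frames by default; ``standardize_targets`` optionally
    z-scores them as well (per frame, population moments).  Frames whose
    proxy (or, with the flag, whose raw signal) is (numerically) constant
    cannot be z-scored; they are skipped with a warning and counted in
    ``n_skipped``.
    """
    if len(frames) and frames.frame_length != matrix.N:
        raise DimensionMismatchError(
            f"frame length {frames.frame_length} != matrix N {matrix.N}"
        )
    X = frames.frames
    Y = X @ matrix.entries.T
    Xt = Y @ matrix.pinv.T
    mus = Xt.mean(axis=1)
    sigmas = Xt.std(axis=1)
    keep = sigmas > _SIGMA_FLOOR
    if standardize_targets:
        keep &= X.std(axis=1) > _SIGMA_FLOOR
    n_skipped = int((~keep).sum())
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} degenerate frame(s) with constant proxy",
            stacklevel=2,
        )
    R = (Xt[keep] - mus[keep, None]) / sigmas[keep, None]
    T = X[keep]
    if standardize_targets:
        T = (T - T.mean(axis=1, keepdims=True)) / T.std(axis=1, keepdims=True)
    return TrainingPairs(
        inputs=R,
        targets=T,
        matrix=matrix,
        split=split,
        n_skipped=n_skipped,
        mus=mus[keep],
        sigmas=sigmas[keep],
    )


def mse_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean over frames of the squared l2 norm of the reconstruction error."""
    P = np.atleast_2d(np.asarray(predictions, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if P.shape != T.shape:
        raise DimensionMismatchError(f"shapes differ: {P.shape} vs {T.shape}")
    if P.shape[0] == 0:
        raise ValueError("empty batch")
    return float(np.mean(np.sum((P - T) ** 2, axis=1)))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _epoch_loss(net: CSResNet, R: np.ndarray, X: np.ndarray, batch_size: int) -> float:
    total = 0.0
    for start in range(0, R.shape[0], batch_size):
        out, _ = net.forward_batch(R[start : start + batch_size])
        total += float(np.sum(np.sum((out - X[start : start + batch_size]) ** 2, axis=1)))
    return total / R.shape[0]


def train(
    net: CSResNet, pairs: TrainingPairs, hp: HyperParams | None = None
) -> tuple[CSResNet, TrainingHistory]:
    """Fit the network in place with mini-batch Adam.

    A ``val_fraction`` carve-out from the pairs (seeded) monitors validation
    loss; training stops early after ``early_stop_patience`` epochs without
    improvement and the best-validation weights are restored.  With
    ``val_fraction == 0`` the training loss is monitored instead.  In
    single-threaded execution the result is fully determined by
    (net init seed, hp.seed, data).
    """
    hp = hp or HyperParams()
    n = len(pairs)
    if n == 0:
        raise ConfigurationError("cannot train on an empty pair set")
    rng = np.random.default_rng(hp.seed)
    n_val = int(np.floor(hp.val_fraction * n + 0.5))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ConfigurationError("validation carve-out left no training examples")
    R_tr, X_tr = pairs.inputs[tr_idx], pairs.targets[tr_idx]
    R_val, X_val = pairs.inputs[val_idx], pairs.targets[val_idx]

    opt = _Adam(net.parameters(), hp.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_params = [p.copy() for p in net.parameters()]
    since_best = 0
    for epoch in range(hp.epochs):
        order = rng.permutation(R_tr.shape[0])
        running = 0.0
        for bstart in range(0, order.size, hp.batch_size):
            idx = order[bstart : bstart + hp.batch_size]
            Rb, Xb = R_tr[idx], X_tr[idx]
            out, caches = net.forward_batch(Rb, train=True)
            err = out - Xb
            batch_loss = float(np.mean(np.sum(err**2, axis=1)))
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(
                    f"non-finite loss {batch_loss} at epoch {epoch}", epoch=epoch,
                    batch=bstart // hp.batch_size,
                )
            running += batch_loss * idx.size
            grads = net.backward_batch(2.0 * err / idx.size, caches)
            if hp.learning_rate > 0:
                opt.step(net.parameters(), grads)
        history.train_loss.append(running / order.size)
        monitored = (
            _epoch_loss(net, R_val, X_val, hp.batch_size)
            if n_val
            else history.train_loss[-1]
        )
        history.val_loss.append(monitored)
        if monitored < best_loss - 1e-12:
            best_loss = monitored
            best_params = [p.copy() for p in net.parameters()]
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= hp.early_stop_patience:
                break
    net.set_parameters(best_params)
    return net, history


# ---------------------------------------------------------------------------
# Estimator / results interface
# ---------------------------------------------------------------------------


class CSResNetModel:
    """Reconstruction model bound to training frames and a sensing matrix.

    Parameters
    ----------
    frames : FrameSet
        Training frames (raw signal, length N each).
    matrix : MeasurementMatrix
        The sensing operator shared by all frames.
    config : ModelConfig, optional
        Network architecture; defaults to the standard stack at the frames'
        length N.
    """

    def __init__(
        self,
        frames: FrameSet,
        matrix: MeasurementMatrix,
        config: ModelConfig | None = None,
    ):
        if frames.frame_length != matrix.N:
            raise DimensionMismatchError(
                f"frame length {frames.frame_length} != matrix N {matrix.N}"
            )
        self.frames = frames
        self.matrix = matrix
        self.config = config or default_model_config(frame_length=frames.frame_length)
        if self.config.frame_length != frames.frame_length:
            raise DimensionMismatchError("model config frame_length != frame length")
        self.pairs = make_pairs(frames, matrix, split="train")

    @classmethod
    def from_recording(cls, recording, frame_seconds: float, matrix, config=None):
        """Build directly from a recording by framing it first."""
        from .synthetic import frame_recording

        return cls(frame_recording(recording, frame_seconds), matrix, config)

    def fit(self, hp: HyperParams | None = None) -> "CSResNetResults":
        """Train the network and return a results object."""
        hp = hp or HyperParams()
        net = CSResNet(self.config)
        t0 = time.perf_counter()
        net, history = train(net, self.pairs, hp)
        elapsed = time.perf_counter() - t0
        return CSResNetResults(self, net, history, hp, elapsed)


class CSResNetResults:
    """Fitted reconstruction network with its training history and diagnostics."""

    def __init__(
        self,
        model: CSResNetModel,
        net: CSResNet,
        history: TrainingHistory,
        hyperparams: HyperParams,
        fit_seconds: float,
    ):
        self.model = model
        self.net = net
        self.history = history
        self.hyperparams = hyperparams
        self.fit_seconds = fit_seconds

    def reconstruct(self, frames: FrameSet) -> np.ndarray:
        """Compress, back-project, z-score and decode frames; returns (n, N)."""
        pairs = make_pairs(frames, self.model.matrix, split="eval")
        out, _ = self.net.forward_batch(pairs.inputs)
        return out

    def reconstruct_measurements(self, Y: np.ndarray) -> np.ndarray:
        """Decode raw measurement vectors (n, M) without access to the originals."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[1] != self.model.matrix.M:
            raise DimensionMismatchError(
                f"measurements have length {Y.shape[1]}, matrix M is {self.model.matrix.M}"
            )
        Xt = Y @ self.model.matrix.pinv.T
        mus = Xt.mean(axis=1, keepdims=True)
        sigmas = Xt.std(axis=1, keepdims=True)
        if np.any(sigmas <= _SIGMA_FLOOR):
            raise TrainingDivergedError("degenerate measurement: constant proxy")
        out, _ = self.net.forward_batch((Xt - mus) / sigmas)
        return out

    def prd(self, frames: FrameSet) -> np.ndarray:
        """Per-frame percentage RMS difference on a frame set."""
        from .evaluation import prd as _prd

        Xhat = self.reconstruct(frames)
        return np.array([_prd(frames.frames[i], Xhat[i]) for i in range(len(frames))])

    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model results."""
        m = self.model.matrix
        h = self.history
        lines = [
            "                      CS-ResNet Reconstruction Results",
            "=" * 72,
            f"Frame length N:        {self.model.config.frame_length:>8d}"
            f"    Measurements M:      {m.M:>8d}",
            f"Compression ratio:     {m.M / m.N:>8.2f}"
            f"    Matrix kind:   {m.kind:>14s}",
            f"Training frames:       {len(self.model.pairs):>8d}"
            f"    Skipped frames:      {self.model.pairs.n_skipped:>8d}",
            f"Parameters:            {self.net.n_parameters():>8d}"
            f"    Epochs run:          {h.n_epochs:>8d}",
            f"Learning rate:         {self.hyperparams.learning_rate:>8.4g}"
            f"    Batch size:          {self.hyperparams.batch_size:>8d}",
            f"Final train loss:      {h.train_loss[-1]:>12.4f}",
            f"Best monitored loss:   {min(h.val_loss):>12.4f}    (epoch {h.best_epoch})",
            f"Fit wall time [s]:     {self.fit_seconds:>12.2f}",
            "=" * 72,
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss curves over epochs; returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, self.history.n_epochs + 1)
        ax.plot(epochs, self.history.train_loss, label="train")
        ax.plot(epochs, self.history.val_loss, label="monitored")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss (mean squared frame error)")
        ax.legend()
        return ax

    def plot_reconstruction(self, frames: FrameSet, index: int = 0, ax=None):
        """Overlay one original frame and its reconstruction."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xhat = self.reconstruct(frames.subset([index]))[0]
        ax.plot(frames.frames[index], label="original", lw=0.8)
        ax.plot(xhat, label="reconstructed", lw=0.8)
        ax.set_xlabel("sample")
        ax.legend()
        return ax

    def save(self, path) -> None:
        self.net.save(path)
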