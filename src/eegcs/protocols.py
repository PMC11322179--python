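"""Canonical desk-scale experiment protocols.

The full-scale protocol mirrors a standard telemonitoring acquisition: 2-s frames
at 250 Hz (N = 500) cut from a 4-channel, 600-s synthetic recording, an
80/20 random split, and sparse-binary sensing at compression ratios
10%...90%.  Training the network at N = 500 over that sweep is a
multi-hour job, so the package also defines one fixed *scaled* protocol for
routine verification: the same generator, sampling rate, split and matrix
family, but 0.512-s frames (N = 128), a 96-s recording per channel
(750 frames total) and at most 30 training epochs.  All seeds fan out from
a single integer so every run is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import prd
from .model import default_model_config
from .sensing import make_sparse_binary_matrix
from .synthetic import FrameSet, RecordingConfig, frame_recording, generate_recording, split_frames
from .training import CSResNetModel, HyperParams

__all__ = [
    "ScaledProtocol",
    "scaled_frames",
    "learning_gate",
]


@dataclass(frozen=True)
class ScaledProtocol:
    """The fixed scaled verification protocol."""

    n_channels: int = 4
    duration_s: float = 96.0
    fs: float = 250.0
    frame_seconds: float = 0.512  # N = 128
    train_fraction: float = 0.8
    epochs: int = 30
    early_stop_patience: int = 10

    @property
    def frame_length(self) -> int:
        return int(round(self.frame_seconds * self.fs))


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def scaled_frames(seed: int, protocol: ScaledProtocol = ScaledProtocol()) -> tuple[FrameSet, FrameSet]:
    """Generate the scaled protocol's train/test frame sets."""
    rec_seed, split_seed = _stage_seeds(seed, 2)
    config = RecordingConfig(
        n_channels=protocol.n_channels,
        duration_s=protocol.duration_s,
        fs=protocol.fs,
        seed=rec_seed,
    )
    frames = frame_recording(generate_recording(config), protocol.frame_seconds)
    return split_frames(frames, protocol.train_fraction, seed=split_seed)


def learning_gate(
    seed: int,
    cr: float,
    protocol: ScaledProtocol = ScaledProtocol(),
    train_frames: FrameSet | None = None,
    test_frames: FrameSet | None = None,
) -> dict:
    """Train the network at one compression ratio under the scaled protocol.

    Returns the mean test PRD of the trained network and of the plain
    pseudo-inverse back-projection under the same matrix, plus bookkeeping.
    Pass pre-built frame sets to share them across compression ratios.
    """
    if train_frames is None or test_frames is None:
        train_frames, test_frames = scaled_frames(seed, protocol)
    matrix_seed, init_seed, train_seed = _stage_seeds(seed + 1, 3)
    N = train_frames.frame_length
    M = int(round(cr * N))
    matrix = make_sparse_binary_matrix(M, N, seed=matrix_seed)

    X_test = test_frames.frames
    proxies = (X_test @ matrix.entries.T) @ matrix.pinv.T
    proxy_prds = [prd(X_test[i], proxies[i]) for i in range(X_test.shape[0])]

    hp = HyperParams(
        epochs=protocol.epochs,
        early_stop_patience=protocol.early_stop_patience,
        seed=train_seed,
    )
    config = default_model_config(frame_length=N, init_seed=init_seed)
    results = CSResNetModel(train_frames, matrix, config).fit(hp)
    net_prds = results.prd(test_frames)
    return {
        "cr": cr,
        "M": M,
        "N": N,
        "mean_prd_cs_resnet": float(np.mean(net_prds)),
        "mean_prd_proxy_only": float(np.mean(proxy_prds)),
        "n_test_frames": len(test_frames),
        "epochs_run": results.history.n_epochs,
        "fit_seconds": results.fit_seconds,
    }
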