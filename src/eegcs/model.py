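"""CS-ResNet: a 1-D dilated-convolution residual network for frame reconstruction.

The network maps the z-scored proxy signal r (length N) straight to an
estimate of the original frame x_hat = H(r), replacing iterative sparse
recovery with a single learned forward pass.  The stack is:

    stem:   1 -> 16 channels, kernel 3, dilation 2, ELU
    2 x residual block, each six dilated conv + ELU layers
            (channels 32, 64, 128, 64, 32, 16; kernels 7, 7, 5, 5, 3, 3;
             dilation 2), output added to the block input (F(x) + x)
    head:   16 -> 1 channel, kernel 3, dilation 2, linear
    dense:  N -> N fully connected output

Dilation spaces the kernel taps d samples apart, so a kernel of size h covers
an effective window h' = h + (h-1)(d-1); symmetric zero-padding
p = d(h-1)/2 keeps the temporal length constant at stride 1.  The whole
network — forward pass, backpropagation and parameter handling — is
self-contained NumPy built on im2col + BLAS matrix products, which keeps the
model dependency-light and bit-reproducible on a single thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DimensionMismatchError

__all__ = [
    "LayerSpec",
    "ModelConfig",
    "ReconstructedFrame",
    "CSResNet",
    "dilated_window",
    "same_padding",
    "build_model",
    "forward",
    "elu",
    "default_model_config",
]


def dilated_window(h: int, d: int) -> int:
    """Effective window size of a dilated kernel: h' = h + (h-1)(d-1)."""
    if not (isinstance(h, (int, np.integer)) and isinstance(d, (int, np.integer))):
        raise ConfigurationError("h and d must be integers")
    if h < 1 or d < 1:
        raise ConfigurationError(f"h and d must be positive, got h={h}, d={d}")
    return int(h + (h - 1) * (d - 1))


def same_padding(h: int, d: int) -> int:
    """Symmetric zero-padding that preserves length at stride 1: p = d(h-1)/2.

    Requires an odd kernel so the padding is integral:
    L_out = L + 2p - (h' - 1) = L  with  h' = h + (h-1)(d-1).
    """
    if h < 1 or d < 1:
        raise ConfigurationError(f"h and d must be positive, got h={h}, d={d}")
    if h % 2 == 0:
        raise ConfigurationError(f"kernel size must be odd for same padding, got {h}")
    return d * (h - 1) // 2


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Exponential linear unit: x for x >= 0, alpha*(exp(x)-1) for x < 0."""
    return np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, fx: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    # d/dx ELU = 1 (x >= 0) else alpha*exp(x) = fx + alpha
    return np.where(x >= 0, 1.0, fx + alpha)


@dataclass(frozen=True)
class LayerSpec:
    """One dilated 1-D convolution layer: channels out, kernel h, dilation d."""

    out_channels: int
    kernel: int
    dilation: int = 2
    activation: str = "elu"

    def __post_init__(self):
        if self.out_channels < 1:
            raise ConfigurationError("out_channels must be >= 1")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ConfigurationError(f"kernel must be odd positive, got {self.kernel}")
        if self.dilation < 1:
            raise ConfigurationError("dilation must be >= 1")
        if self.activation not in ("elu", "none"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")


_DEFAULT_BLOCK = (
    LayerSpec(32, 7), LayerSpec(64, 7), LayerSpec(128, 5),
    LayerSpec(64, 5), LayerSpec(32, 3), LayerSpec(16, 3),
)


@dataclass(frozen=True)
class ModelConfig:
    """Declarative description of the full CS-ResNet stack."""

    frame_length: int
    stem: LayerSpec = LayerSpec(16, 3)
    residual_block: tuple = _DEFAULT_BLOCK
    n_blocks: int = 2
    head_conv: LayerSpec = LayerSpec(1, 3, activation="none")
    init_seed: int = 0

    def __post_init__(self):
        if self.frame_length < 1:
            raise ConfigurationError("frame_length must be >= 1")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        block = tuple(self.residual_block)
        object.__setattr__(self, "residual_block", block)
        if block[-1].out_channels != self.stem.out_channels:
            raise ConfigurationError(
                "skip addition needs the last residual layer to emit "
                f"{self.stem.out_channels} channels, got {block[-1].out_channels}"
            )
        if self.head_conv.out_channels != 1:
            raise ConfigurationError("head conv must emit a single channel")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        def spec(s):
            return LayerSpec(**s) if isinstance(s, dict) else s
        return cls(
            frame_length=d["frame_length"],
            stem=spec(d["stem"]),
            residual_block=tuple(spec(s) for s in d["residual_block"]),
            n_blocks=d.get("n_blocks", 2),
            head_conv=spec(d["head_conv"]),
            init_seed=d.get("init_seed", 0),
        )


def default_model_config(frame_length: int = 500, init_seed: int = 0) -> ModelConfig:
    """The default CS-ResNet stack at a given frame length."""
    return ModelConfig(frame_length=frame_length, init_seed=init_seed)


@dataclass(frozen=True)
class ReconstructedFrame:
    """The network's estimate x_hat of one original frame."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise DimensionMismatchError("reconstructed frame must be 1-D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("reconstructed frame contains non-finite values")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.shape[0]


class _Conv1d:
    """Dilated same-padded 1-D convolution with explicit backprop."""

    def __init__(self, in_channels: int, spec: LayerSpec, rng: np.random.Generator):
        self.in_channels = in_channels
        self.spec = spec
        h, d = spec.kernel, spec.dilation
        self.pad = same_padding(h, d)
        fan_in = in_channels * h
        limit = np.sqrt(3.0 / fan_in)  # variance-scaling (fan-in) uniform
        self.W = rng.uniform(-limit, limit, size=(spec.out_channels, in_channels, h))
        self.b = np.zeros(spec.out_channels)

    @property
    def params(self):
        return [self.W, self.b]

    def _im2col(self, X: np.ndarray) -> np.ndarray:
        # X: (B, C, L) -> columns (B, C, L, h) sampling taps d apart
        h, d = self.spec.kernel, self.spec.dilation
        Xp = np.pad(X, ((0, 0), (0, 0), (self.pad, self.pad)))
        h_eff = dilated_window(h, d)
        win = np.lib.stride_tricks.sliding_window_view(Xp, h_eff, axis=2)
        return win[..., ::d]

    def forward(self, X: np.ndarray, train: bool = False):
        cols = self._im2col(X)  # (B, C, L, h)
        Y = np.tensordot(self.W, cols, axes=([1, 2], [1, 3]))  # (O, B, L)
        Y = np.transpose(Y, (1, 0, 2)) + self.b[None, :, None]
        cache = cols if train else None
        return Y, cache

    def backward(self, dY: np.ndarray, cols: np.ndarray, L: int):
        # dY: (B, O, L); cols: (B, C, L, h)
        h, d = self.spec.kernel, self.spec.dilation
        dW = np.tensordot(dY, cols, axes=([0, 2], [0, 2]))  # (O, C, h)
        db = dY.sum(axis=(0, 2))
        G = np.tensordot(self.W, dY, axes=([0], [1]))  # (C, h, B, L)
        B = dY.shape[0]
        dXp = np.zeros((B, self.in_channels, L + 2 * self.pad))
        for k in range(h):
            dXp[:, :, k * d : k * d + L] += np.transpose(G[:, k], (1, 0, 2))
        dX = dXp[:, :, self.pad : self.pad + L] if self.pad else dXp
        return dX, [dW, db]


class _Dense:
    """Fully connected N -> N output layer."""

    def __init__(self, n: int, rng: np.random.Generator):
        limit = np.sqrt(3.0 / n)
        self.W = rng.uniform(-limit, limit, size=(n, n))
        self.b = np.zeros(n)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray):
        return X @ self.W.T + self.b

    def backward(self, dY: np.ndarray, X: np.ndarray):
        return dY @ self.W, [dY.T @ X, dY.sum(axis=0)]


class CSResNet:
    """The assembled network: stem -> residual blocks -> head -> dense.

    Weights are initialized deterministically from ``config.init_seed``.
    ``forward`` accepts a (B, N) batch or a single length-N vector.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        c = 1
        self.stem = _Conv1d(c, config.stem, rng)
        c = config.stem.out_channels
        self.blocks: list[list[_Conv1d]] = []
        for _ in range(config.n_blocks):
            layers = []
            cin = c
            for spec in config.residual_block:
                layers.append(_Conv1d(cin, spec, rng))
                cin = spec.out_channels
            if cin != c:
                raise ConfigurationError("residual block changes channel count")
            self.blocks.append(layers)
        self.head = _Conv1d(c, config.head_conv, rng)
        self.dense = _Dense(config.frame_length, rng)

    # -- parameter plumbing ------------------------------------------------

    def _layers(self):
        yield self.stem
        for block in self.blocks:
            yield from block
        yield self.head
        yield self.dense

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        it = iter(params)
        for layer in self._layers():
            layer.W = next(it).copy()
            layer.b = next(it).copy()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward ------------------------------------------------

    def _check_input(self, r) -> tuple[np.ndarray, bool]:
        X = np.asarray(r, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.ndim != 2 or X.shape[1] != self.config.frame_length:
            raise DimensionMismatchError(
                f"expected frames of length {self.config.frame_length}, got shape {X.shape}"
            )
        return X, single

    def forward_batch(self, R: np.ndarray, train: bool = False):
        """Run a (B, N) batch through the stack; optionally keep caches."""
        X, _ = self._check_input(R)
        caches = {"inputs": []} if train else None
        h = X[:, None, :]  # (B, 1, N)
        z, cols = self.stem.forward(h, train)
        a = elu(z)
        if train:
            caches["stem"] = (cols, z, a)
        h = a
        block_caches = []
        for block in self.blocks:
            inp = h
            layer_caches = []
            for conv in block:
                z, cols = conv.forward(h, train)
                a = elu(z)
                layer_caches.append((cols, z, a))
                h = a
            h = h + inp  # skip connection: F(x) + x
            block_caches.append(layer_caches)
        if train:
            caches["blocks"] = block_caches
        z_head, cols_head = self.head.forward(h, train)
        feat = z_head[:, 0, :]  # (B, N)
        out = self.dense.forward(feat)
        if train:
            caches["head"] = (cols_head, feat)
        return out, caches

    def forward(self, r) -> ReconstructedFrame | np.ndarray:
        """Map normalized proxy frame(s) to reconstructed frame(s)."""
        vals = getattr(r, "values", r)
        X, single = self._check_input(vals)
        out, _ = self.forward_batch(X)
        return ReconstructedFrame(values=out[0]) if single else out

    def backward_batch(self, dOut: np.ndarray, caches: dict) -> list[np.ndarray]:
        """Backpropagate a gradient w.r.t. the output; returns grads
        ordered like :meth:`parameters`."""
        L = self.config.frame_length
        cols_head, feat = caches["head"]
        dFeat, dense_grads = self.dense.backward(dOut, feat)
        dH = dFeat[:, None, :]  # (B, 1, N)
        dH, head_grads = self.head.backward(dH, cols_head, L)
        block_grads_rev = []
        for block, layer_caches in zip(reversed(self.blocks), reversed(caches["blocks"])):
            d_skip = dH  # gradient flows unchanged through the identity path
            d = dH
            grads_rev = []
            for conv, (cols, z, a) in zip(reversed(block), reversed(layer_caches)):
                d = d * _elu_grad(z, a)
                d, g = conv.backward(d, cols, L)
                grads_rev.append(g)
            dH = d + d_skip
            block_grads_rev.append(list(reversed(grads_rev)))
        cols, z, a = caches["stem"]
        d = dH * _elu_grad(z, a)
        _, stem_grads = self.stem.backward(d, cols, L)
        grads: list[np.ndarray] = []
        grads.extend(stem_grads)
        for g_block in reversed(block_grads_rev):
            for g in g_block:
                grads.extend(g)
        grads.extend(head_grads)
        grads.extend(dense_grads)
        return grads

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights as an .npz checkpoint with a JSON config sidecar."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_name(path.name + ".npz")
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)
        sidecar = path.with_name(path.name + ".json")
        sidecar.write_text(json.dumps(self.config.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CSResNet":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_name(path.name + ".npz")
        sidecar = path.with_name(path.name + ".json")
        config = ModelConfig.from_dict(json.loads(sidecar.read_text()))
        net = cls(config)
        with np.load(path) as data:
            params = [data[f"p{i}"] for i in range(len(data.files))]
        net.set_parameters(params)
        return net


def build_model(config: ModelConfig) -> CSResNet:
    """Construct a CS-ResNet with deterministic initial weights."""
    return CSResNet(config)


def forward(model: CSResNet, r):
    """Functional alias for :meth:`CSResNet.forward`."""
    return model.forward(r)
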