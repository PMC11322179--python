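"""Seeded synthetic EEG-like recordings and fixed-length framing.

Real scalp EEG used for telemonitoring experiments is band-limited
(0.5-100 Hz), dominated by rhythmic activity in the classical delta, theta,
alpha and beta bands, rides on a 1/f ("pink") background, and may carry a
residual mains component.  The generator emulates exactly that statistical
picture — per-channel band sinusoids with randomized frequency, amplitude
and phase, plus seeded pink noise and an optional line sinusoid — so the
whole compression/reconstruction pipeline is testable without any external
dataset.  It does not attempt event-related potentials, artifacts or
nonstationarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .sensing import SignalFrame

__all__ = [
    "RecordingConfig",
    "Recording",
    "FrameSet",
    "DEFAULT_RHYTHM_BANDS",
    "generate_recording",
    "frame_recording",
    "split_frames",
]

# (low Hz, high Hz, (min amplitude, max amplitude)) in microvolt-scale units;
# plausible awake scalp-EEG magnitudes for the four classical rhythms.
DEFAULT_RHYTHM_BANDS: tuple[tuple[float, float, tuple[float, float]], ...] = (
    (0.5, 4.0, (20.0, 40.0)),   # delta
    (4.0, 8.0, (10.0, 20.0)),   # theta
    (8.0, 13.0, (15.0, 30.0)),  # alpha
    (13.0, 30.0, (5.0, 10.0)),  # beta
)


@dataclass(frozen=True)
class RecordingConfig:
    """Declarative description of a synthetic multichannel recording."""

    n_channels: int
    duration_s: float
    fs: float = 250.0
    rhythm_bands: tuple = DEFAULT_RHYTHM_BANDS
    pink_noise_scale: float = 5.0
    line_hz: float | None = 50.0
    line_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigurationError("duration_s and fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ConfigurationError(
                f"duration_s * fs must be a positive integer, got {n}"
            )
        for low, high, (amin, amax) in self.rhythm_bands:
            if low >= high:
                raise ConfigurationError(f"band low {low} >= high {high}")
            if high >= self.fs / 2:
                raise ConfigurationError(
                    f"band edge {high} Hz >= Nyquist {self.fs / 2} Hz"
                )
            if amin < 0 or amax < amin:
                raise ConfigurationError(f"bad amplitude range ({amin}, {amax})")
        if self.pink_noise_scale < 0 or self.line_amplitude < 0:
            raise ConfigurationError("noise scales must be nonnegative")
        if self.line_hz is not None and not (0 < self.line_hz < self.fs / 2):
            raise ConfigurationError("line_hz must lie in (0, fs/2)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class Recording:
    """A channels x time array of synthetic EEG with its generating config."""

    samples: np.ndarray
    fs: float
    config: RecordingConfig

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ConfigurationError("samples must be channels x time")
        if not np.all(np.isfinite(samples)):
            raise ValueError("recording contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class FrameSet:
    """Non-overlapping, consecutive length-N frames cut from a recording.

    ``provenance[i]`` records the (channel, start-sample) origin of frame i.
    Trailing partial windows are discarded so that every frame shares one N
    (and therefore one measurement matrix).
    """

    frames: np.ndarray  # (n_frames, N)
    frame_length: int
    provenance: tuple[tuple[int, int], ...]

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 2 or frames.shape[1] != self.frame_length:
            raise ConfigurationError(
                f"frames must be (n, {self.frame_length}), got {frames.shape}"
            )
        if len(self.provenance) != frames.shape[0]:
            raise ConfigurationError("provenance length must match frame count")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> SignalFrame:
        return SignalFrame(values=self.frames[i])

    def subset(self, indices) -> "FrameSet":
        idx = np.asarray(indices, dtype=int)
        return FrameSet(
            frames=self.frames[idx],
            frame_length=self.frame_length,
            provenance=tuple(self.provenance[i] for i in idx),
        )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance pink (1/f power) noise via spectral shaping of white noise.

    White Gaussian noise is filtered with a 1/sqrt(f) amplitude profile in the
    rFFT domain (DC bin forced to 0), then rescaled to population std 1.
    """
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spectrum * shaping, n=n)
    sd = np.std(pink)
    return pink / sd if sd > 0 else pink


def generate_recording(config: RecordingConfig) -> Recording:
    """Synthesize a multichannel band-limited recording under a fixed seed.

    Each channel is the sum of one sinusoid per rhythm band — frequency drawn
    uniformly inside the band, amplitude uniformly inside the band's range,
    phase uniform on [0, 2pi), all per channel — plus scaled pink noise and,
    if configured, a mains-frequency sinusoid.  The draw order is fixed, so a
    given (config, seed) always produces bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.arange(n) / config.fs
    samples = np.zeros((config.n_channels, n))
    for ch in range(config.n_channels):
        x = np.zeros(n)
        for low, high, (amin, amax) in config.rhythm_bands:
            f = rng.uniform(low, high)
            a = rng.uniform(amin, amax)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x += a * np.sin(2.0 * np.pi * f * t + phase)
        if config.pink_noise_scale > 0:
            x += config.pink_noise_scale * _pink_noise(rng, n)
        if config.line_hz is not None and config.line_amplitude > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x += config.line_amplitude * np.sin(2.0 * np.pi * config.line_hz * t + phase)
        samples[ch] = x
    return Recording(samples=samples, fs=config.fs, config=config)


def frame_recording(recording: Recording, frame_seconds: float) -> FrameSet:
    """Cut every channel into consecutive non-overlapping length-N windows.

    N = frame_seconds * fs must be a positive integer (e.g. 2 s at 250 Hz
    gives N = 500).  Frames are taken from sample 0 in steps of N; a trailing
    window shorter than N is discarded.
    """
    n_float = frame_seconds * recording.fs
    if abs(n_float - round(n_float)) > 1e-9 or round(n_float) < 1:
        raise ConfigurationError(
            f"frame_seconds * fs must be a positive integer, got {n_float}"
        )
    N = int(round(n_float))
    T = recording.n_samples
    per_channel = T // N
    frames = []
    provenance = []
    for ch in range(recording.n_channels):
        for k in range(per_channel):
            frames.append(recording.samples[ch, k * N : (k + 1) * N])
            provenance.append((ch, k * N))
    frames_arr = (
        np.array(frames) if frames else np.empty((0, N))
    )
    return FrameSet(frames=frames_arr, frame_length=N, provenance=tuple(provenance))


def split_frames(
    frames: FrameSet, train_fraction: float, seed: int = 0
) -> tuple[FrameSet, FrameSet]:
    """Randomly partition a frame set into train and test subsets.

    The split is disjoint and exhaustive; |train| = round(train_fraction * n)
    (half-up), and the permutation is fixed by the seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ConfigurationError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = len(frames)
    if n < 2:
        raise ConfigurationError("need at least 2 frames to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    perm = np.random.default_rng(seed).permutation(n)
    return frames.subset(np.sort(perm[:n_train])), frames.subset(np.sort(perm[n_train:]))
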