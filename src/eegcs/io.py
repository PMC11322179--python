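"""Reading and writing recordings, matrices and frames.

Two interchangeable on-disk forms are supported for recordings: a plain CSV
(one column per channel, header ``ch0..chK``, one row per sample) and an
``.npz`` array container.  Both carry a JSON sidecar with the sampling rate
and the full generating config, so any saved recording can be re-created or
audited.  Measurement matrices use the same container + sidecar convention
(kind, M, N, seed, ones-per-column), making experiments bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sensing import MeasurementMatrix
from .synthetic import Recording, RecordingConfig

__all__ = [
    "save_recording_csv",
    "load_recording_csv",
    "save_recording_npz",
    "load_recording_npz",
    "save_matrix",
    "load_matrix",
    "save_frames_csv",
    "load_frames_csv",
]


def _config_to_dict(config: RecordingConfig) -> dict:
    d = dataclasses.asdict(config)
    d["rhythm_bands"] = [
        [low, high, list(amp)] for low, high, amp in config.rhythm_bands
    ]
    return d


def _config_from_dict(d: dict) -> RecordingConfig:
    bands = tuple((b[0], b[1], tuple(b[2])) for b in d["rhythm_bands"])
    return RecordingConfig(**{**d, "rhythm_bands": bands})


def _write_sidecar(path: Path, recording: Recording) -> None:
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps({"fs": recording.fs, "config": _config_to_dict(recording.config)}, indent=2)
    )


def _read_sidecar(path: Path) -> dict:
    return json.loads(path.with_name(path.name + ".json").read_text())


def save_recording_csv(recording: Recording, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    columns = {f"ch{i}": recording.samples[i] for i in range(recording.n_channels)}
    pd.DataFrame(columns).to_csv(path, index=False)
    _write_sidecar(path, recording)
    return path


def load_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    config = _config_from_dict(meta["config"])
    return Recording(samples=df.to_numpy().T, fs=meta["fs"], config=config)


def save_recording_npz(recording: Recording, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, samples=recording.samples, fs=recording.fs)
    _write_sidecar(path, recording)
    return path


def load_recording_npz(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    meta = _read_sidecar(path)
    with np.load(path) as data:
        samples = data["samples"]
    return Recording(samples=samples, fs=meta["fs"], config=_config_from_dict(meta["config"]))


def save_matrix(matrix: MeasurementMatrix, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, entries=matrix.entries)
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "kind": matrix.kind,
                "M": matrix.M,
                "N": matrix.N,
                "seed": matrix.seed,
                "ones_per_column": matrix.ones_per_column,
            },
            indent=2,
        )
    )
    return path


def load_matrix(path: str | Path) -> MeasurementMatrix:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    meta = json.loads(path.with_name(path.name + ".json").read_text())
    with np.load(path) as data:
        entries = data["entries"]
    return MeasurementMatrix(
        entries=entries,
        kind=meta["kind"],
        seed=meta["seed"],
        ones_per_column=meta["ones_per_column"],
    )


def save_frames_csv(frames: np.ndarray, path: str | Path) -> Path:
    """Write frames (one row per frame) as headerless CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.atleast_2d(frames), delimiter=",")
    return path


def load_frames_csv(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return arr
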