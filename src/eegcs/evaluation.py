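"""PRD metric and the compression-ratio sweep harness.

Reconstruction quality is scored with the percentage root-mean-square
difference

    PRD = 100 * ||x_hat - x||_2 / ||x||_2     [%]

(0 for perfect reconstruction; 100 for the all-zero reconstruction).  The
sweep harness runs a grid of compression ratios against a set of
reconstruction methods — pseudo-inverse back-projection only, OMP, CoSaMP,
the trained network, or any user-plugged reconstructor — and aggregates
per-frame PRD (mean and standard deviation over the test frames) plus
informational per-frame wall time into a tabular report.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DimensionMismatchError
from .baselines import SparsifyingBasis, dct_basis, reconstruct_classical
from .model import ModelConfig, default_model_config
from .sensing import (
    MeasurementMatrix,
    make_gaussian_matrix,
    make_sparse_binary_matrix,
)
from .synthetic import FrameSet
from .training import CSResNetModel, HyperParams

__all__ = [
    "prd",
    "SweepReport",
    "sweep",
    "write_report",
    "read_report",
    "plot_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = ["cr", "method", "mean_prd", "std_prd", "n_frames", "mean_seconds", "seed"]

KNOWN_METHODS = ("proxy_only", "omp", "cosamp", "cs_resnet")


def prd(x, x_hat) -> float:
    """Percentage root-mean-square difference between a frame and its estimate."""
    x = np.asarray(getattr(x, "values", x), dtype=float)
    x_hat = np.asarray(getattr(x_hat, "values", x_hat), dtype=float)
    if x.shape != x_hat.shape:
        raise DimensionMismatchError(f"shapes differ: {x.shape} vs {x_hat.shape}")
    ref = np.linalg.norm(x)
    if ref <= 0:
        raise ValueError("PRD is undefined for a zero reference frame")
    return float(100.0 * np.linalg.norm(x_hat - x) / ref)


@dataclass
class SweepReport:
    """Per-(CR, method) PRD statistics with a config echo.

    Every requested cell is present; a failed method is marked with
    ``failed=True``, NaN statistics and the error message, so one broken
    method never aborts the sweep.
    """

    table: pd.DataFrame
    config: dict = field(default_factory=dict)

    def cell(self, cr: float, method: str) -> pd.Series:
        rows = self.table[
            (np.isclose(self.table["cr"], cr)) & (self.table["method"] == method)
        ]
        if rows.empty:
            raise KeyError(f"no cell for cr={cr}, method={method}")
        return rows.iloc[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SweepReport):
            return NotImplemented
        a = self.table.drop(columns=["mean_seconds"]).reset_index(drop=True)
        b = other.table.drop(columns=["mean_seconds"]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, check_exact=False)
        except AssertionError:
            return False
        return self.config == other.config


def _default_matrix_factory(kind: str):
    def factory(M: int, N: int, seed: int) -> MeasurementMatrix:
        if M == N:
            # lossless limit: identity sensing, used in tests at CR = 1
            return MeasurementMatrix(entries=np.eye(N), kind="identity", seed=seed)
        if kind == "gaussian":
            return make_gaussian_matrix(M, N, seed=seed)
        return make_sparse_binary_matrix(M, N, seed=seed)

    return factory


def sweep(
    train_frames: FrameSet | None,
    test_frames: FrameSet,
    cr_list,
    methods,
    seed: int = 0,
    *,
    matrix_kind: str = "sparse_binary",
    matrix_factory=None,
    basis: SparsifyingBasis | None = None,
    sparsity: int | None = None,
    model_config: ModelConfig | None = None,
    hyperparams: HyperParams | None = None,
    reconstructors: dict | None = None,
) -> SweepReport:
    """Run the full CR x method comparison protocol on a fixed test set.

    For each compression ratio, one measurement matrix with M = round(CR * N)
    rows is drawn from a seed derived deterministically from ``seed``, shared
    by every method and every frame at that CR.  ``cs_resnet`` additionally
    trains the network on ``train_frames`` before reconstructing the test
    set.  ``reconstructors`` may map extra method names to callables
    ``f(matrix, Y) -> (n, N) array`` to benchmark external algorithms.
    """
    cr_list = list(cr_list)
    methods = list(methods)
    reconstructors = reconstructors or {}
    for m in methods:
        if m not in KNOWN_METHODS and m not in reconstructors:
            raise ConfigurationError(f"unknown method {m!r}")
    for cr in cr_list:
        if not (0.0 < cr <= 1.0):
            raise ConfigurationError(f"compression ratio must lie in (0, 1], got {cr}")
    if "cs_resnet" in methods and (train_frames is None or len(train_frames) == 0):
        raise ConfigurationError("cs_resnet requires training frames")

    N = test_frames.frame_length
    factory = matrix_factory or _default_matrix_factory(matrix_kind)
    basis = basis or (dct_basis(N) if {"omp", "cosamp"} & set(methods) else None)
    X_test = test_frames.frames
    seed_seq = np.random.SeedSequence(seed)
    cr_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(len(cr_list))]

    rows = []
    for cr, cr_seed in zip(cr_list, cr_seeds):
        M = int(round(cr * N))
        matrix = factory(M, N, cr_seed)
        Y = X_test @ matrix.entries.T
        for method in methods:
            row = {
                "cr": cr, "method": method, "mean_prd": np.nan, "std_prd": np.nan,
                "n_frames": len(test_frames), "mean_seconds": np.nan,
                "seed": cr_seed, "failed": False, "error": "",
            }
            try:
                t0 = time.perf_counter()
                X_hat = _reconstruct_all(
                    method, matrix, Y, train_frames, basis, sparsity,
                    model_config, hyperparams, cr_seed, reconstructors,
                )
                elapsed = time.perf_counter() - t0
                prds = np.array([prd(X_test[i], X_hat[i]) for i in range(len(X_test))])
                row.update(
                    mean_prd=float(prds.mean()),
                    std_prd=float(prds.std()),
                    mean_seconds=elapsed / max(len(X_test), 1),
                )
            except Exception as exc:  # noqa: BLE001 — cell-level isolation is the contract
                row.update(failed=True, error=f"{type(exc).__name__}: {exc}")
            rows.append(row)
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS + ["failed", "error"])
    config = {
        "N": N, "cr_list": cr_list, "methods": methods, "seed": seed,
        "matrix_kind": matrix_kind, "sparsity": sparsity,
        "n_test_frames": len(test_frames),
        "n_train_frames": len(train_frames) if train_frames is not None else 0,
    }
    return SweepReport(table=table, config=config)


def _reconstruct_all(
    method, matrix, Y, train_frames, basis, sparsity, model_config, hyperparams,
    cr_seed, reconstructors,
):
    if method in reconstructors:
        return np.asarray(reconstructors[method](matrix, Y), dtype=float)
    if method == "proxy_only":
        return Y @ matrix.pinv.T
    if method in ("omp", "cosamp"):
        return np.stack(
            [
                reconstruct_classical(matrix, basis, y, algo=method, K=sparsity).values
                for y in Y
            ]
        )
    if method == "cs_resnet":
        config = model_config or default_model_config(
            frame_length=matrix.N, init_seed=cr_seed
        )
        if config.frame_length != matrix.N:
            raise DimensionMismatchError("model config frame_length != matrix N")
        hp = hyperparams or HyperParams(seed=cr_seed)
        results = CSResNetModel(train_frames, matrix, config).fit(hp)
        return results.reconstruct_measurements(Y)
    raise ConfigurationError(f"unknown method {method!r}")


def write_report(report: SweepReport, path: str | Path) -> Path:
    """Write a report as CSV (one row per cell) plus a JSON config echo.

    ``path`` is the CSV target; the JSON sidecar sits next to it.  The pair
    round-trips losslessly through :func:`read_report` (timing excepted).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(report.config, indent=2))
    return path


def read_report(path: str | Path) -> SweepReport:
    path = Path(path)
    table = pd.read_csv(path)
    if "error" in table.columns:
        table["error"] = table["error"].fillna("")
    sidecar = path.with_suffix(".json")
    config = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SweepReport(table=table, config=config)


def plot_report(report: SweepReport, ax=None):
    """PRD versus compression ratio, one line per method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = report.table[~report.table["failed"]]
    for method, group in ok.groupby("method"):
        g = group.sort_values("cr")
        ax.errorbar(g["cr"], g["mean_prd"], yerr=g["std_prd"], marker="o", label=method)
    ax.set_xlabel("compression ratio M/N")
    ax.set_ylabel("PRD [%]")
    ax.legend()
    return ax
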