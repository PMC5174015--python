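"""Reading and writing of pipeline artifacts.

Signals come in as plain text (one amplitude per row, or ``time,amplitude``
pairs); adjacency matrices go out as dense CSV grids or sparse tab-separated
edge lists; feature matrices and classification reports are CSV / YAML.

All in-memory arrays use 0-based indexing.  Serialized edge lists use 1-based
node numbers, which is the convention the rest of the package documents for
anything written to disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import InvariantViolationError, SignalFormatError, SignalParseError

#: decimal places emitted by the text writers (round trips are lossless at
#: this precision)
DEFAULT_PRECISION = 6


@dataclass
class RawSignal:
    """A single-channel EMG amplitude series.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in microvolts; finite, length >= 1.
    sampling_rate : float
        Samples per second, > 0.
    source_id : str
        Free-text label for provenance.
    """

    samples: np.ndarray
    sampling_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise SignalFormatError("signal must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.samples)):
            raise SignalFormatError("signal contains non-finite samples")
        if not self.sampling_rate > 0:
            raise SignalFormatError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


def read_signal(path, format: str = "auto", sampling_rate: float | None = None) -> RawSignal:
    """Read an amplitude series from a plain-text file.

    ``single-column`` files carry one amplitude per row; ``two-column`` files
    carry ``time,amplitude`` rows with a monotonically increasing time base
    from which the sampling rate is inferred (median time step).  ``auto``
    picks the layout from the first row.

    Raises
    ------
    SignalParseError
        On a non-numeric row (the message names the line) or an empty file.
    SignalFormatError
        If the time base jitters by more than 1% or the inferred rate
        disagrees with a supplied one by more than 1%.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise SignalParseError(f"{path}: non-numeric row at line {lineno}: {line!r}")
    if not rows:
        raise SignalParseError(f"{path}: empty signal file")

    ncol = len(rows[0])
    if format == "auto":
        format = "two-column" if ncol >= 2 else "single-column"
    if any(len(r) != ncol for r in rows):
        raise SignalFormatError(f"{path}: inconsistent column count")

    if format == "single-column":
        if sampling_rate is None:
            raise SignalFormatError("sampling_rate required for single-column input")
        samples = np.array([r[0] for r in rows])
        rate = float(sampling_rate)
    else:
        t = np.array([r[0] for r in rows])
        samples = np.array([r[1] for r in rows])
        if len(t) < 2:
            if sampling_rate is None:
                raise SignalFormatError("cannot infer rate from a single row")
            rate = float(sampling_rate)
        else:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise SignalFormatError(f"{path}: time column not monotonically increasing")
            step = float(np.median(dt))
            if np.max(np.abs(dt - step)) > 0.01 * step:
                raise SignalFormatError(f"{path}: time step jitter exceeds 1%")
            rate = 1.0 / step
            if sampling_rate is not None and not math.isclose(rate, sampling_rate, rel_tol=0.01):
                raise SignalFormatError(
                    f"{path}: inferred rate {rate:g} disagrees with supplied {sampling_rate:g}"
                )
    return RawSignal(samples=samples, sampling_rate=rate, source_id=str(path))


def write_signal(signal: RawSignal, path, precision: int = DEFAULT_PRECISION) -> None:
    """Write one amplitude per row at the given decimal precision."""
    np.savetxt(path, signal.samples, fmt=f"%.{precision}f")


def write_adjacency(W: np.ndarray, path, mode: str = "dense",
                    precision: int = DEFAULT_PRECISION) -> None:
    """Serialize a weighted adjacency matrix.

    ``dense`` writes an N x N comma-separated grid (the canonical
    interchange); ``edge-list`` writes ``i<TAB>j<TAB>weight`` rows for i < j
    with nonzero weight only, 1-based node numbers.
    """
    W = np.asarray(W, dtype=float)
    _check_square_symmetric(W)
    if mode == "dense":
        np.savetxt(path, W, fmt=f"%.{precision}f", delimiter=",")
    elif mode == "edge-list":
        with open(path, "w") as fh:
            iu, ju = np.nonzero(np.triu(W, k=1))
            for i, j in zip(iu, ju):
                fh.write(f"{i + 1}\t{j + 1}\t{W[i, j]:.{precision}f}\n")
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")


def read_adjacency(path, mode: str = "dense", n_nodes: int | None = None) -> np.ndarray:
    """Deserialize an adjacency matrix written by :func:`write_adjacency`."""
    if mode == "dense":
        W = np.loadtxt(path, delimiter=",", ndmin=2)
        _check_square_symmetric(W)
        return W
    if mode == "edge-list":
        with open(path) as fh:
            text = fh.read().strip()
        rows = (np.array([[float(v) for v in line.split()] for line in
                          text.splitlines()])
                if text else np.empty((0, 3)))
        if rows.size == 0:
            if n_nodes is None:
                raise SignalFormatError("empty edge list needs an explicit n_nodes")
            return np.zeros((n_nodes, n_nodes))
        n = n_nodes or int(rows[:, :2].max())
        W = np.zeros((n, n))
        for i, j, w in rows:
            W[int(i) - 1, int(j) - 1] = w
            W[int(j) - 1, int(i) - 1] = w
        return W
    raise ValueError(f"unknown adjacency mode {mode!r}")


def _check_square_symmetric(W: np.ndarray) -> None:
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvariantViolationError("adjacency matrix must be square")
    if not np.allclose(W, W.T):
        raise InvariantViolationError("adjacency matrix must be symmetric")


@dataclass
class FeatureMatrix:
    """M features x N epochs grid with names, ids and optional labels."""

    values: np.ndarray                     # shape (M, N)
    feature_names: list[str]
    epoch_ids: list[str]
    labels: list | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.feature_names):
            raise InvariantViolationError("row count must equal feature count")
        if self.values.shape[1] != len(self.epoch_ids):
            raise InvariantViolationError("column count must equal epoch count")
        if np.isnan(self.values).any():
            raise InvariantViolationError("feature matrix may not contain NaN")

    @property
    def X(self) -> np.ndarray:
        """Samples-by-features view for sklearn estimators."""
        return self.values.T

    @property
    def y(self) -> np.ndarray | None:
        return None if self.labels is None else np.asarray(self.labels)


def write_feature_matrix(fm: FeatureMatrix, path,
                         precision: int = DEFAULT_PRECISION) -> None:
    """CSV with header ``epoch_id,label,<feature names...>``, one epoch per row."""
    labels = fm.labels if fm.labels is not None else [""] * len(fm.epoch_ids)
    df = pd.DataFrame(fm.values.T, columns=fm.feature_names)
    df.insert(0, "label", labels)
    df.insert(0, "epoch_id", fm.epoch_ids)
    df.to_csv(path, index=False, float_format=f"%.{precision}f")


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c not in ("epoch_id", "label")]
    labels = None
    if "label" in df.columns and df["label"].notna().all():
        labels = df["label"].tolist()
    return FeatureMatrix(
        values=df[names].to_numpy().T,
        feature_names=names,
        epoch_ids=[str(e) for e in df["epoch_id"]],
        labels=labels,
    )


def write_report(report: dict, path) -> None:
    """Emit a structured key-value document (YAML)."""
    with open(path, "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)


def read_report(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
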