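"""Epoch detection and normalization.

An EMG recording alternates between muscle-response bursts (epochs) and
near-flat non-signal stretches.  Epoch borders are found by scanning outward
from each supra-threshold peak of the rectified signal until its envelope
slope stays below a tolerance for a minimum run of samples — the "zero
slope" region separating bursts.  Each detected window is then full-wave
rectified and divided by its peak so the peak amplitude is exactly 1.

Slopes are measured on a short moving-average envelope of the rectified
signal (``smooth_ms``, default 2 ms): on a noisy baseline the raw
sample-to-sample slope virtually never stays inside a tolerance band, so the
zero-slope criterion only works on a lightly smoothed trace.  Setting
``smooth_ms=0`` recovers the raw per-sample rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateEpochError
from .io import RawSignal

CLASS_NAMES = ("normal", "neuropathy", "myopathy")

DEFAULT_AMP_THRESHOLD_FRAC = 0.3
DEFAULT_SLOPE_EPS_FRAC = 0.01     # of the global rectified max, per sample
DEFAULT_MIN_GAP_MS = 5.0
DEFAULT_SMOOTH_MS = 2.0


@dataclass(frozen=True)
class EpochWindow:
    """Inclusive [start, end] sample window with its rectified-peak index."""

    start: int
    end: int
    peak: int

    def __post_init__(self) -> None:
        if not (self.start <= self.peak <= self.end):
            raise ValueError("window must satisfy start <= peak <= end")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Epoch:
    """A peak-normalized amplitude sequence, the unit of analysis.

    ``x`` holds dimensionless amplitudes in [0, 1] (or [-1, 1] when built
    with ``rectify=False``) with max(|x|) == 1 exactly.
    """

    x: np.ndarray
    window: EpochWindow
    label: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.size < 2:
            raise DegenerateEpochError("epoch must have length >= 2")
        if not np.isclose(np.max(np.abs(self.x)), 1.0):
            raise DegenerateEpochError("epoch peak must equal 1")

    def __len__(self) -> int:
        return self.x.size

    @property
    def peak_offset(self) -> int:
        """Index of the (first) peak sample within ``x``."""
        return int(np.argmax(np.abs(self.x)))


def _envelope(rect: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return rect
    kernel = np.ones(win) / win
    # same-length moving average; edge samples average over a shorter span
    pad = np.pad(rect, (win // 2, win - 1 - win // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_epochs(
    signal: RawSignal,
    amp_threshold_frac: float = DEFAULT_AMP_THRESHOLD_FRAC,
    slope_eps_frac: float = DEFAULT_SLOPE_EPS_FRAC,
    min_gap_ms: float = DEFAULT_MIN_GAP_MS,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> list[EpochWindow]:
    """Locate muscle-response windows in a raw signal.

    A window is opened around every local maximum of the rectified signal
    whose amplitude reaches ``amp_threshold_frac`` of the global rectified
    maximum; its borders are the nearest samples, scanning outward from the
    peak, where the envelope slope magnitude stays below
    ``slope_eps_frac * global_max`` for ``min_gap_ms`` worth of consecutive
    samples.  Windows closer than the same gap are merged.  Returns sorted,
    non-overlapping windows; an empty list if nothing crosses threshold.
    """
    if not 0 < amp_threshold_frac < 1:
        raise ValueError("amp_threshold_frac must be in (0, 1)")
    s = signal.samples
    if s.size < 3:
        return []
    rect = np.abs(s)
    gmax = rect.max()
    if gmax == 0 or np.ptp(rect) == 0:
        return []
    threshold = amp_threshold_frac * gmax
    eps = slope_eps_frac * gmax
    min_gap = max(1, int(round(min_gap_ms * signal.sampling_rate / 1000.0)))
    smooth = max(1, int(round(smooth_ms * signal.sampling_rate / 1000.0))) if smooth_ms > 0 else 1

    env = _envelope(rect, smooth)
    quiet = np.abs(np.diff(env)) < eps   # quiet[i]: slope between samples i, i+1

    peaks = _local_maxima(rect, threshold)
    if peaks.size == 0:
        return []

    raw: list[tuple[int, int]] = []
    n = s.size
    for p in peaks:
        start = _scan_border(quiet, p, min_gap, direction=-1)
        end = _scan_border(quiet, p, min_gap, direction=+1, n=n)
        raw.append((start, end))

    # merge overlapping windows and windows separated by less than min_gap
    raw.sort()
    merged: list[list[int]] = []
    for start, end in raw:
        if merged and start <= merged[-1][1] + min_gap:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])

    windows = []
    for start, end in merged:
        peak = start + int(np.argmax(rect[start:end + 1]))
        windows.append(EpochWindow(start=start, end=end, peak=peak))
    return windows


def _local_maxima(rect: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of strict-or-plateau local maxima with amplitude >= threshold."""
    from scipy.signal import find_peaks

    idx, _ = find_peaks(rect, height=threshold)
    # find_peaks never reports the first/last sample; include them if they
    # dominate their neighbor and cross threshold
    extra = []
    if rect[0] >= threshold and rect[0] > rect[1]:
        extra.append(0)
    if rect[-1] >= threshold and rect[-1] > rect[-2]:
        extra.append(rect.size - 1)
    return np.sort(np.concatenate([idx, np.array(extra, dtype=int)]))


def _scan_border(quiet: np.ndarray, peak: int, min_gap: int,
                 direction: int, n: int | None = None) -> int:
    """Border sample on one side of a peak.

    Scanning outward, the border is the near end of the first run of
    ``min_gap`` consecutive quiet slopes; absent such a run, the signal edge.
    """
    run = 0
    if direction < 0:
        for i in range(peak - 1, -1, -1):     # slope i sits between samples i, i+1
            run = run + 1 if quiet[i] else 0
            if run >= min_gap:
                return i + min_gap            # near (peak-side) end of the run
        return 0
    assert n is not None
    for i in range(peak, quiet.size):
        run = run + 1 if quiet[i] else 0
        if run >= min_gap:
            return i - min_gap + 1
    return n - 1


def normalize_epoch(signal: RawSignal, window: EpochWindow,
                    rectify: bool = True, label: str | None = None) -> Epoch:
    """Full-wave rectify a window and divide by its peak amplitude.

    With ``rectify=False`` signed amplitudes are preserved and divided by the
    rectified peak (so max(|x|) == 1).
    """
    seg = signal.samples[window.start:window.end + 1]
    peak_amp = np.max(np.abs(seg))
    if peak_amp == 0:
        raise DegenerateEpochError("window peak amplitude is zero")
    x = (np.abs(seg) if rectify else seg) / peak_amp
    # pin the peak to exactly 1 against floating-point division error
    x[np.argmax(np.abs(x))] = np.sign(x[np.argmax(np.abs(x))]) * 1.0 if not rectify else 1.0
    return Epoch(x=x, window=window, label=label)


def decimate_epoch(epoch: Epoch, factor: int) -> Epoch:
    """Subsample an epoch on a peak-aligned grid.

    Keeps every ``factor``-th sample on the grid through the peak (so the
    peak is always retained) plus the first sample, then renormalizes so the
    maximum is exactly 1.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return epoch
    n = len(epoch)
    peak = epoch.peak_offset
    keep = np.unique(np.concatenate([[0], np.arange(peak % factor, n, factor)]))
    if keep.size < 2:
        raise DegenerateEpochError("decimated epoch would have fewer than 2 samples")
    x = epoch.x[keep]
    x = x / np.max(np.abs(x))
    x[np.argmax(np.abs(x))] = 1.0
    return Epoch(x=x, window=epoch.window, label=epoch.label)


class EpochSegmenter(TransformerMixin, BaseEstimator):
    """Transformer mapping raw signals to normalized (optionally decimated) epochs.

    Parameters mirror :func:`detect_epochs`, :func:`normalize_epoch` and
    :func:`decimate_epoch`.  ``transform`` takes a list of
    :class:`~myovis.io.RawSignal` and returns a flat list of
    :class:`Epoch`; labels are carried over from each signal's ``source_id``
    prefix when it names a class, or can be supplied explicitly via ``y``
    at ``fit`` time (one label per signal).
    """

    def __init__(self, amp_threshold_frac: float = DEFAULT_AMP_THRESHOLD_FRAC,
                 slope_eps_frac: float = DEFAULT_SLOPE_EPS_FRAC,
                 min_gap_ms: float = DEFAULT_MIN_GAP_MS,
                 smooth_ms: float = DEFAULT_SMOOTH_MS,
                 decimation_factor: int = 1,
                 rectify: bool = True):
        self.amp_threshold_frac = amp_threshold_frac
        self.slope_eps_frac = slope_eps_frac
        self.min_gap_ms = min_gap_ms
        self.smooth_ms = smooth_ms
        self.decimation_factor = decimation_factor
        self.rectify = rectify

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X, y=None) -> list[Epoch]:
        labels = list(y) if y is not None else [self._label_of(sig) for sig in X]
        epochs: list[Epoch] = []
        for sig, label in zip(X, labels):
            for w in detect_epochs(sig, self.amp_threshold_frac,
                                   self.slope_eps_frac, self.min_gap_ms,
                                   self.smooth_ms):
                ep = normalize_epoch(sig, w, rectify=self.rectify, label=label)
                if self.decimation_factor > 1:
                    ep = decimate_epoch(ep, self.decimation_factor)
                epochs.append(ep)
        return epochs

    @staticmethod
    def _label_of(sig: RawSignal) -> str | None:
        for name in CLASS_NAMES:
            if sig.source_id and sig.source_id.split("/")[-1].startswith(name):
                return name
        return None
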