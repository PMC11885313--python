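"""Signal conditioning: band-pass, line-noise notch, causal sliding z-score,
and two-stream alignment by cross-correlation of a shared sync channel.

All filters are Butterworth, applied zero-phase (forward-backward,
``sosfiltfilt``) because the downstream analyses are offline and
phase-sensitive — a causal filter would bias Hilbert phase estimates used for
phase-amplitude coupling. Zero-phase application squares the magnitude
response, so the effective attenuation order is twice the design order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)

SD_FLOOR = 1e-12  # relative floor applied to a zero-variance window


class AlignmentError(RuntimeError):
    """Raised when the cross-correlation peak is not distinguishable from chance."""


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "bandpass" | "bandstop"
    edges: tuple[float, float]
    order: int = 8
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        lo, hi = self.edges
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"filter edges {self.edges} must satisfy 0 < low < high < fs/2")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def _apply_sos(x: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low_hz: float = 0.5,
    high_hz: float = 1000.0,
    order: int = 8,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass along the last axis (defaults: 0.5–1000 Hz, order 8)."""
    FilterSpec("bandpass", (low_hz, high_hz), order, zero_phase).validate(fs)
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return _apply_sos(np.asarray(x, float), sos, zero_phase)


def notch_filter(
    x: np.ndarray,
    fs: float,
    base_hz: float = 60.0,
    n_harmonics: int = 1,
    half_width_hz: float = 1.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Band-stop filters at the line frequency and, optionally, its harmonics.

    ``n_harmonics`` counts the stop bands including the base frequency:
    ``n_harmonics=3`` removes 60, 120 and 180 Hz.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    y = np.asarray(x, float)
    for k in range(1, n_harmonics + 1):
        f0 = base_hz * k
        edges = (f0 - half_width_hz, f0 + half_width_hz)
        FilterSpec("bandstop", edges, order, zero_phase).validate(fs)
        sos = signal.butter(order, edges, btype="bandstop", fs=fs, output="sos")
        y = _apply_sos(y, sos, zero_phase)
    return y


def sliding_zscore(x: np.ndarray, fs: float, window_s: float = 30.0) -> np.ndarray:
    """Causal z-scoring: each sample standardized by the mean/SD of the
    preceding ``window_s`` seconds.

    The first ``window_s`` of output, which has no full preceding window, is
    standardized by the first full window's statistics. A zero-variance
    window gets an SD floor (logged) instead of dividing by zero.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    squeeze = np.asarray(x).ndim == 1
    x = np.atleast_2d(np.asarray(x, float))
    n = x.shape[-1]
    w = int(round(window_s * fs))
    if n < w:
        raise ValueError("recording shorter than the z-score window")

    c1 = np.cumsum(x, axis=-1)
    c2 = np.cumsum(x * x, axis=-1)
    # trailing-window sums ending just before sample i, for i >= w
    s1 = np.empty_like(x)
    s2 = np.empty_like(x)
    s1[:, w:] = c1[:, w - 1 : -1] - np.concatenate(
        [np.zeros((x.shape[0], 1)), c1[:, : n - w - 1]], axis=-1
    )
    s2[:, w:] = c2[:, w - 1 : -1] - np.concatenate(
        [np.zeros((x.shape[0], 1)), c2[:, : n - w - 1]], axis=-1
    )
    # first full window's statistics for the leading stretch
    s1[:, :w] = c1[:, w - 1 : w]
    s2[:, :w] = c2[:, w - 1 : w]
    mean = s1 / w
    var = np.maximum(s2 / w - mean**2, 0.0)
    sd = np.sqrt(var)
    scale = max(float(np.std(x)), 1.0)
    floor = SD_FLOOR * scale
    n_floored = int(np.sum(sd < floor))
    if n_floored:
        log.warning("sliding_zscore: SD floor applied to %d samples", n_floored)
    sd = np.maximum(sd, floor)
    z = (x - mean) / sd
    return z[0] if squeeze else z


def align_streams(
    sync_a: np.ndarray,
    sync_b: np.ndarray,
    fs: float,
    n_null: int = 200,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Lag (s) of stream *b* relative to stream *a*, from the cross-correlation
    of their shared pulse channel, refined to sub-sample precision by
    parabolic interpolation of the peak.

    A positive return value means ``b`` is delayed: ``b(t) ≈ a(t − lag)``.
    Significance is assessed against a null of circularly shifted copies of
    ``b``; if the observed peak does not exceed the (1−alpha) quantile of the
    null peaks, :class:`AlignmentError` is raised.
    """
    a = np.asarray(sync_a, float) - np.mean(sync_a)
    b = np.asarray(sync_b, float) - np.mean(sync_b)
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        raise AlignmentError("a sync stream is constant")
    c = signal.correlate(b, a, mode="full", method="fft") / denom
    lags = signal.correlation_lags(len(b), len(a), mode="full")
    k = int(np.argmax(c))
    peak = c[k]

    rng = np.random.default_rng(seed)
    # shuffled control: permute ~1000-sample blocks of b, destroying any true
    # alignment while preserving amplitude statistics and pulse density
    block = max(1, min(1000, len(b) // 20))
    n_blocks = len(b) // block
    null_peaks = np.empty(n_null)
    for i in range(n_null):
        perm = rng.permutation(n_blocks)
        bs = b[: n_blocks * block].reshape(n_blocks, block)[perm].ravel()
        null_peaks[i] = np.max(signal.correlate(bs, a, mode="full", method="fft")) / denom
    if peak <= np.quantile(null_peaks, 1 - alpha):
        raise AlignmentError("cross-correlation peak not significant vs shuffled control")

    # parabolic refinement around the integer-lag peak
    delta = 0.0
    if 0 < k < len(c) - 1:
        y0, y1, y2 = c[k - 1], c[k], c[k + 1]
        d = y0 - 2 * y1 + y2
        if d < 0:
            delta = 0.5 * (y0 - y2) / d
    return (lags[k] + delta) / fs
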