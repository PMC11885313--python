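"""Welch periodograms, sliding spectral features, and IRASA.

IRASA (irregular-resampling auto-spectral analysis) separates the power
spectrum of an electrophysiological signal into an aperiodic (fractal)
component that follows the power law ``P ∝ 1/f^β`` and an oscillatory
component containing the spectral peaks. For each resampling factor ``h``
the signal is resampled by ``h`` and by ``1/h``; a power law is invariant
under the geometric mean of the resulting spectral pair while narrow-band
peaks are displaced to ``f·h`` and ``f/h``. Taking the median of the
geometric means across a fan of factors (default 1.1 … 1.9 in steps of
0.05, 17 factors) therefore leaves the aperiodic component; subtracting it
from the total PSD yields the oscillatory residue, which may legitimately
be negative and is never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

DEFAULT_IRASA_FACTORS: tuple[float, ...] = tuple(np.round(np.arange(1.1, 1.901, 0.05), 2))


# ---------------------------------------------------------------------------
# Welch estimates


def welch_psd(
    segment: np.ndarray,
    fs: float,
    resolution_hz: float = 0.5,
    band: tuple[float, float] | None = (0.5, 100.0),
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (V²/Hz) on a grid at ``resolution_hz``.

    Sub-windows are Hann-tapered with 50% overlap and a nominal length of
    ``1/resolution_hz`` seconds; a segment shorter than that is estimated
    with a single zero-padded taper so the requested grid is still produced.
    """
    x = np.asarray(segment, float)
    if x.shape[-1] == 0:
        raise ValueError("empty segment")
    nfft = int(round(fs / resolution_hz))
    nperseg = min(x.shape[-1], nfft)
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
        detrend="constant",
    )
    if band is not None:
        lo, hi = band
        m = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        freqs, psd = freqs[m], psd[..., m]
    return freqs, psd


@dataclass
class PSDSeries:
    """Sliding-window PSD: ``power`` is channels × windows × freqs."""

    times: np.ndarray  # window centers, s
    freqs: np.ndarray  # Hz
    power: np.ndarray  # V²/Hz (a.u. after z-scoring)
    window_s: float
    overlap: float


def sliding_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.8,
    band: tuple[float, float] | None = (0.5, 100.0),
    resolution_hz: float = 0.5,
) -> PSDSeries:
    """Welch PSD in sliding windows; stride = ``window_s·(1−overlap)``.

    The defaults (1-s window, 80% overlap) produce one spectrum every 0.2 s.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    x = np.atleast_2d(np.asarray(x, float))
    n = x.shape[-1]
    wlen = int(round(window_s * fs))
    stride = window_s * (1 - overlap)
    step = int(round(stride * fs))
    if wlen > n:
        raise ValueError("window longer than recording")
    n_windows = (n - wlen) // step + 1
    starts = np.arange(n_windows) * step
    out = None
    for j, s0 in enumerate(starts):
        freqs, psd = welch_psd(x[:, s0 : s0 + wlen], fs, resolution_hz, band)
        if out is None:
            out = np.empty((x.shape[0], n_windows, freqs.size))
        out[:, j, :] = psd
    times = (starts + wlen / 2) / fs
    return PSDSeries(times=times, freqs=freqs, power=out, window_s=window_s, overlap=overlap)


def mean_band_power(
    psd_series: PSDSeries,
    band_lo: float = 100.0,
    band_hi: float = 500.0,
    subband_width: float = 50.0,
    channels: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """The decoder feature: per window, the mean over equal sub-band means
    over the selected channels (defaults: 100–500 Hz in 50-Hz sub-bands).

    Returns ``(times, feature)`` with one value per window, in the PSD's
    units (V²/Hz).
    """
    n_sub = (band_hi - band_lo) / subband_width
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError("sub-bands must tile [band_lo, band_hi]")
    n_sub = int(round(n_sub))
    power = psd_series.power
    if channels is not None:
        channels = np.asarray(channels, int)
        if channels.size == 0:
            raise ValueError("empty channel set")
        power = power[channels]
    f = psd_series.freqs
    sub_means = []
    for i in range(n_sub):
        lo = band_lo + i * subband_width
        hi = lo + subband_width
        m = (f >= lo - 1e-9) & ((f < hi - 1e-9) if i < n_sub - 1 else (f <= hi + 1e-9))
        if not np.any(m):
            raise ValueError(f"no frequencies in sub-band [{lo}, {hi}] Hz")
        sub_means.append(power[:, :, m].mean(axis=-1))
    feature = np.mean(sub_means, axis=0).mean(axis=0)  # over sub-bands, then channels
    return psd_series.times, feature


# ---------------------------------------------------------------------------
# IRASA


@dataclass
class IrasaDecomposition:
    """Total/aperiodic/oscillatory spectra per channel plus fitted exponents."""

    freqs: np.ndarray
    total: np.ndarray  # channels × freqs
    aperiodic: np.ndarray
    oscillatory: np.ndarray  # total − aperiodic, elementwise (may be negative)
    resampling_factors: tuple[float, ...]
    window_s: float
    overlap: float
    beta: np.ndarray | None = None  # filled by fit_aperiodic_exponent
    fit_band: tuple[float, float] | None = None


def _resampled_psd(
    x: np.ndarray, fs: float, factor_num: int, factor_den: int, nperseg: int, overlap: float
) -> tuple[np.ndarray, np.ndarray]:
    """PSD of the signal resampled by num/den, labeled at the *original* fs.

    Resampling by h while keeping the nominal rate compresses frequencies by
    h and scales the density by h, so a power law C·f^−β maps to
    C·h^(1−β)·f^−β; the up/down pair's geometric mean restores C·f^−β.
    The Welch window is scaled by the same factor so the segment count (and
    hence estimator variance) matches the total PSD's.
    """
    y = signal.resample_poly(x, factor_num, factor_den, axis=-1)
    h = factor_num / factor_den
    nper = int(round(nperseg * h))
    freqs, psd = signal.welch(
        y,
        fs=fs,
        window="blackman",
        nperseg=nper,
        noverlap=int(round(nper * overlap)),
        detrend="constant",
    )
    return freqs, psd


def _regrid(freqs: np.ndarray, psd: np.ndarray, grid: np.ndarray, half_width: float) -> np.ndarray:
    """Average native Welch bins within ±half_width of each printed-grid point."""
    out = np.empty(psd.shape[:-1] + (grid.size,))
    for i, f0 in enumerate(grid):
        m = np.abs(freqs - f0) <= half_width + 1e-9
        out[..., i] = psd[..., m].mean(axis=-1)
    return out


def irasa(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.5, 30.0),
    window_s: float = 4.0,
    overlap: float = 0.75,
    factors: tuple[float, ...] = DEFAULT_IRASA_FACTORS,
    resolution_hz: float = 0.5,
) -> IrasaDecomposition:
    """Separate aperiodic and oscillatory PSD components.

    The signal is segmented into ``window_s`` windows (default 4 s — two
    cycles of the 0.5 Hz band edge) with 75% overlap; for each resampling
    factor the geometric mean of the up/down-resampled spectral pair is
    computed, and the median across factors is the aperiodic component.
    Spectra are reported on the printed grid at ``resolution_hz`` increments
    (band endpoints included), each point averaging the native Welch bins
    within half an increment.
    """
    for h in factors:
        if h <= 1:
            raise ValueError("resampling factors must exceed 1 (pairs straddle 1)")
    if band[1] * max(factors) >= fs / 2:
        raise ValueError("band upper edge × max(factor) must stay below Nyquist")
    x = np.atleast_2d(np.asarray(x, float))
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError("recording shorter than one IRASA window")
    noverlap = int(round(nperseg * overlap))
    # Blackman taper: steep 1/f spectra leak through Hann sidelobes from the
    # strong sub-band content, biasing the lowest octave of the decomposition
    freqs, total = signal.welch(
        x, fs=fs, window="blackman", nperseg=nperseg, noverlap=noverlap, detrend="constant"
    )
    gms = np.empty((len(factors),) + total.shape)
    for i, h in enumerate(factors):
        frac = Fraction(round(h * 100), 100)
        f_up, p_up = _resampled_psd(x, fs, frac.numerator, frac.denominator, nperseg, overlap)
        f_dn, p_dn = _resampled_psd(x, fs, frac.denominator, frac.numerator, nperseg, overlap)
        up = np.stack([np.interp(freqs, f_up, p) for p in p_up])
        dn = np.stack([np.interp(freqs, f_dn, p) for p in p_dn])
        gms[i] = np.sqrt(up * dn)
    aperiodic = np.median(gms, axis=0)
    n_steps = int(round((band[1] - band[0]) / resolution_hz))
    grid = band[0] + np.arange(n_steps + 1) * resolution_hz
    total = _regrid(freqs, total, grid, resolution_hz / 2)
    aperiodic = _regrid(freqs, aperiodic, grid, resolution_hz / 2)
    freqs = grid
    return IrasaDecomposition(
        freqs=freqs,
        total=total,
        aperiodic=aperiodic,
        oscillatory=total - aperiodic,
        resampling_factors=tuple(factors),
        window_s=window_s,
        overlap=overlap,
    )


def fit_aperiodic_exponent(
    decomp_or_freqs,
    aperiodic: np.ndarray | None = None,
    fit_band: tuple[float, float] = (1.0, 30.0),
) -> np.ndarray:
    """Aperiodic exponent β per channel from the least-squares slope of
    log P vs log f over ``fit_band`` (β = −slope).

    Accepts either an :class:`IrasaDecomposition` (whose ``beta`` field is
    filled in) or an explicit ``(freqs, aperiodic)`` pair.
    """
    if isinstance(decomp_or_freqs, IrasaDecomposition):
        decomp = decomp_or_freqs
        freqs, spect = decomp.freqs, decomp.aperiodic
    else:
        decomp = None
        freqs, spect = np.asarray(decomp_or_freqs, float), np.atleast_2d(aperiodic)
    spect = np.atleast_2d(spect)
    m = (freqs >= fit_band[0] - 1e-9) & (freqs <= fit_band[1] + 1e-9) & (freqs > 0)
    if m.sum() < 3:
        raise ValueError("fewer than 3 frequencies in the fit band")
    sub = spect[:, m]
    if np.any(sub <= 0):
        raise ValueError("aperiodic spectrum must be positive on the fit band")
    lf = np.log(freqs[m])
    betas = np.empty(sub.shape[0])
    for c in range(sub.shape[0]):
        slope, _ = np.polyfit(lf, np.log(sub[c]), 1)
        betas[c] = -slope
    if decomp is not None:
        decomp.beta = betas
        decomp.fit_band = fit_band
    return betas
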