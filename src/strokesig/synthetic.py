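"""Seeded synthetic recording sessions with the statistical structure the
offline analyses assume, plus ground truth for parameter-recovery tests.

The generator emulates, per array, 1/f^β LFP background with a
distance-graded exponent (arrays nearer the stroke steeper), narrow
oscillatory peaks (a ~0.73 Hz delta peak and alpha/beta-range activity), a
broadband high-frequency noise floor scaled so the grasp decoder's
100–500 Hz feature sits inside the study's open-state range, event-locked
70–450 Hz power increases around hand-closing events, injectable
delta-phase → high-gamma amplitude coupling, inhomogeneous-Poisson spike
trains with pre-closing rate ramps and coordinated cross-channel bursts,
aperture traces exercising every clause of the event-validity rules, and
eight-direction center-out trials with cosine-tuned firing.

LFP synthesis is by spectral shaping of white noise (inverse FFT of a
target amplitude spectrum); event and coupling modulations are applied as
multiplicative envelopes on the band-limited 70–450 Hz component, so the
spectrum IRASA must decompose — and the closed-form phase-binned amplitude
distribution PAC must recover — are both known exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .events import EVENT_COLUMNS
from .preprocess import bandpass_filter
from .session import APERTURE_FS, SessionBundle

log = logging.getLogger(__name__)

DEFAULT_LABELS = ("L1", "L2", "R1", "R2")  # ordered farthest → closest to stroke
# exponents graded with distance to the stroke: closer arrays carry more
# low-frequency power (steeper 1/f)
DEFAULT_BETAS = (1.5, 1.7, 2.3, 2.5)


class ConfigError(ValueError):
    """Invalid synthetic-session configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic session. All rates and durations are
    non-negative; ``pac_strength`` lies in [0, 1]."""

    n_arrays: int = 2
    channels_per_array: int = 64
    fs_lfp: float = 2000.0
    duration_s: float = 120.0
    array_labels: tuple[str, ...] | None = None
    # spectrum
    aperiodic_beta_per_array: tuple[float, ...] | None = None
    aperiodic_amplitude: float = 2000.0  # V²/Hz at 1 Hz
    noise_floor: float = 1.5  # broadband floor, V²/Hz; puts the baseline
    # decoder feature inside the study's 0.5–3 V²/Hz open range
    osc_peaks: tuple[tuple[float, float, float], ...] = (
        (0.73, 0.15, 1500.0),
        (12.0, 2.5, 40.0),
        (21.0, 3.0, 15.0),
    )  # (center Hz, σ Hz, peak height V²/Hz)
    # event-locked gamma and coupling
    gamma_event_gain: float = 8.0  # power multiplier on gamma_band around closings
    gamma_band: tuple[float, float] = (70.0, 450.0)
    gamma_arrays: tuple[str, ...] | None = None  # default: the two far arrays
    pac_strength: float = 0.0  # ∈ [0, 1]
    pac_delta_hz: float = 2.5
    pac_delta_bw: float = 0.5
    # spikes
    baseline_rate: float = 10.0  # spikes/s
    pre_close_gain: float = 5.0  # rate multiplier reached at closing onset
    n_responsive: int = 70
    burst_rate_per_min: float = 2.0
    burst_gain: float = 6.0
    burst_duration_s: float = 0.3
    burst_channel_fraction: float = 0.3
    # center-out
    tuning_depth: float = 0.8
    n_tuned: int = 16
    movement_gain: float = 2.0
    n_trials_per_direction: int = 3
    trial_period_s: float = 3.0
    # aperture schedule
    n_clean_closings: int = 5
    n_pause_resume: int = 0
    n_stalled: int = 0
    n_low_start: int = 0
    inter_block_hold_s: float = 6.0
    aperture_noise: float = 0.1  # % per sample
    # sync / alignment
    sync_rate_hz: float = 1.0
    stream_lag_s: float = 0.0
    seed: int = 0

    @property
    def labels(self) -> tuple[str, ...]:
        if self.array_labels is not None:
            return self.array_labels
        return DEFAULT_LABELS[: self.n_arrays]

    @property
    def betas(self) -> tuple[float, ...]:
        if self.aperiodic_beta_per_array is not None:
            return tuple(self.aperiodic_beta_per_array)
        return DEFAULT_BETAS[: self.n_arrays]

    @property
    def n_channels(self) -> int:
        return self.n_arrays * self.channels_per_array

    @property
    def channel_array(self) -> list[str]:
        return [lab for lab in self.labels for _ in range(self.channels_per_array)]

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration must be positive")
        if not (0.0 <= self.pac_strength <= 1.0):
            raise ConfigError("pac_strength must lie in [0, 1]")
        if len(self.betas) != self.n_arrays:
            raise ConfigError("aperiodic_beta_per_array length must equal n_arrays")
        if len(self.labels) != self.n_arrays:
            raise ConfigError("array_labels length must equal n_arrays")
        if self.tuning_depth < 0:
            raise ConfigError("tuning_depth must be non-negative")
        for name in (
            "baseline_rate",
            "burst_rate_per_min",
            "burst_duration_s",
            "gamma_event_gain",
            "sync_rate_hz",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.gamma_arrays is not None:
            unknown = set(self.gamma_arrays) - set(self.labels)
            if unknown:
                raise ConfigError(f"unknown array label(s) {sorted(unknown)}")

    @property
    def gamma_array_set(self) -> tuple[str, ...]:
        if self.gamma_arrays is not None:
            return self.gamma_arrays
        return self.labels[: min(2, self.n_arrays)]


@dataclass
class SyntheticGroundTruth:
    """What the generator planted, for recovery tests."""

    planted_events: pd.DataFrame
    responsive_channel_ids: set[int]
    true_beta_per_array: dict[str, float]
    true_pac_strength: float
    preferred_direction: np.ndarray | None = None  # rad, NaN where untuned
    tuning_depth: np.ndarray | None = None
    stream_lag_s: float = 0.0

    def validate(self, duration_s: float, n_channels: int) -> None:
        if len(self.planted_events):
            if (self.planted_events["onset_s"] < 0).any() or (
                self.planted_events["end_s"] > duration_s
            ).any():
                raise ValueError("planted event outside session duration")
        if any(i >= n_channels or i < 0 for i in self.responsive_channel_ids):
            raise ValueError("responsive channel id outside the channel set")


# ---------------------------------------------------------------------------
# Aperture trace


class _ApertureBuilder:
    def __init__(self, fs: float = APERTURE_FS, start: float = 100.0):
        self.fs = fs
        self.vals: list[float] = [start]
        self.rows: list[dict] = []

    @property
    def t(self) -> float:
        return (len(self.vals) - 1) / self.fs

    def ramp(self, target: float, duration: float) -> None:
        n = max(1, int(round(duration * self.fs)))
        start = self.vals[-1]
        self.vals.extend(np.linspace(start, target, n + 1)[1:].tolist())

    def hold(self, duration: float) -> None:
        n = int(round(duration * self.fs))
        self.vals.extend([self.vals[-1]] * n)

    def mark(self, etype, onset, end, start_ap, end_ap, tag) -> None:
        self.rows.append(
            {
                "event_type": etype,
                "onset_s": onset,
                "end_s": end,
                "start_aperture": start_ap,
                "end_aperture": end_ap,
                "admitted_by": tag,
            }
        )


def _block_clean(b: _ApertureBuilder) -> None:
    t0 = b.t
    b.ramp(0.0, 0.8)
    b.mark("close", t0, b.t, 100.0, 0.0, "reached_full_close")
    b.hold(1.2)
    t1 = b.t
    b.ramp(100.0, 0.8)
    b.mark("open", t1, b.t, 0.0, 100.0, "reached_full_open")


def _block_pause_resume(b: _ApertureBuilder) -> None:
    # 100 → 50, hold, 50 → 0: the *latter* sweep defines the closing onset
    b.ramp(50.0, 0.5)
    b.hold(1.0)
    t1 = b.t
    b.ramp(0.0, 0.5)
    b.mark("close", t1, b.t, 100.0, 0.0, "reached_full_close")
    b.hold(1.2)
    # mirrored pause-resume opening: 0 → 60, hold, 60 → 100
    b.ramp(60.0, 0.4)
    b.hold(1.0)
    t2 = b.t
    b.ramp(100.0, 0.4)
    b.mark("open", t2, b.t, 0.0, 100.0, "reached_full_open")


def _block_stalled(b: _ApertureBuilder) -> None:
    # closing that stalls above 30% open, then returns: no valid event either way
    b.ramp(45.0, 0.5)
    b.hold(1.0)
    b.ramp(100.0, 0.6)


def _block_low_start(b: _ApertureBuilder) -> None:
    # valid close, partial (invalid) reopen to 75%, invalid close from 75%,
    # then a valid full open
    t0 = b.t
    b.ramp(0.0, 0.8)
    b.mark("close", t0, b.t, 100.0, 0.0, "reached_full_close")
    b.hold(1.0)
    b.ramp(75.0, 0.5)  # invalid opening: never reaches 80%
    b.hold(1.0)
    b.ramp(0.0, 0.5)  # invalid closing: starts below 80% open
    b.hold(1.0)
    t1 = b.t
    b.ramp(100.0, 0.8)
    b.mark("open", t1, b.t, 0.0, 100.0, "reached_full_open")


def generate_aperture_trace(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Aperture trace (percent open at 20 samples/s) plus the ground-truth
    event table the detector must recover.

    The schedule interleaves clean, pause-and-resume, stalled (invalid) and
    low-start (invalid) candidate blocks per the config counts; invalid
    candidates plant no events.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    blocks = (
        [_block_clean] * config.n_clean_closings
        + [_block_pause_resume] * config.n_pause_resume
        + [_block_stalled] * config.n_stalled
        + [_block_low_start] * config.n_low_start
    )
    order = rng.permutation(len(blocks))
    b = _ApertureBuilder()
    b.hold(2.0)
    for i in order:
        blocks[i](b)
        b.hold(config.inter_block_hold_s)
    needed = b.t
    n_total = int(round(config.duration_s * APERTURE_FS)) + 1
    if len(b.vals) > n_total:
        raise ConfigError(
            f"duration {config.duration_s} s too short for the event schedule "
            f"(needs ≥ {needed:.1f} s)"
        )
    vals = np.array(b.vals + [b.vals[-1]] * (n_total - len(b.vals)))
    if config.aperture_noise > 0:
        vals = vals + rng.normal(0.0, config.aperture_noise, vals.size)
    vals = np.clip(vals, 0.0, 100.0)
    events = pd.DataFrame(b.rows, columns=EVENT_COLUMNS)
    events = events.sort_values("onset_s", ignore_index=True)
    return vals, events


# ---------------------------------------------------------------------------
# LFP


def _shaped_noise(
    rng: np.random.Generator, n: int, fs: float, target_psd
) -> np.ndarray:
    """Gaussian noise whose one-sided PSD follows ``target_psd(f)`` (V²/Hz)."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    s = np.asarray(target_psd(freqs), float)
    amp = np.sqrt(np.maximum(s, 0.0) * fs * n / 2.0)
    z = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2)
    spec = amp * z
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real * np.sqrt(2)
    return np.fft.irfft(spec, n=n)


def _aperiodic_psd(beta: float, amplitude: float, floor: float, peaks):
    def target(f):
        # power law continued below the analysis band (flattened only under
        # 0.25 Hz) so resampled spectral pairs near the band edge still see
        # power-law content
        fsafe = np.maximum(f, 0.25)
        s = amplitude / fsafe**beta + floor
        for center, sigma, height in peaks:
            s = s + height * np.exp(-((f - center) ** 2) / (2 * sigma**2))
        return s

    return target


def _event_envelope(
    n: int,
    fs: float,
    onsets: np.ndarray,
    ends: np.ndarray,
    rise_s: float = 0.25,
    pre_s: float = 0.25,
    post_s: float = 0.45,
) -> np.ndarray:
    """0→1 envelope raised from just before each onset to just after its end,
    with raised-cosine edges."""
    env = np.zeros(n)
    t = np.arange(n) / fs
    for t0, t1 in zip(onsets, ends):
        a, bnd = t0 - pre_s, t1 + post_s
        core = (t >= a) & (t <= bnd)
        env[core] = 1.0
        lead = (t >= a - rise_s) & (t < a)
        env[lead] = np.maximum(env[lead], 0.5 * (1 + np.cos(np.pi * (a - t[lead]) / rise_s)))
        trail = (t > bnd) & (t <= bnd + rise_s)
        env[trail] = np.maximum(env[trail], 0.5 * (1 + np.cos(np.pi * (t[trail] - bnd) / rise_s)))
    return env


def generate_lfp(
    config: SyntheticConfig,
    events: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multichannel LFP (channels × samples, float32, volts).

    Per array the background spectrum is ``A/f^β`` plus the configured
    oscillatory peaks and a broadband floor. On the designated gamma arrays
    the 70–450 Hz component is multiplied (in power) by ``gamma_event_gain``
    in a window around each closing onset. With ``pac_strength`` s > 0 a
    narrow delta component d(t) is added and the 70–450 Hz amplitude is
    scaled by ``(1 − s) + s·(1 + cos φ_d)/2`` where φ_d is d's phase.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fs = config.fs_lfp
    n = int(round(config.duration_s * fs))
    closes = events[events["event_type"] == "close"] if len(events) else events
    close_onsets = closes["onset_s"].to_numpy() if len(events) else np.array([])
    close_ends = closes["end_s"].to_numpy() if len(events) else np.array([])
    if close_onsets.size and close_ends.max() > config.duration_s:
        raise ConfigError("events extend beyond the session duration")

    env = None
    if close_onsets.size and config.gamma_event_gain != 1.0:
        env = _event_envelope(n, fs, close_onsets, close_ends)

    out = np.empty((config.n_channels, n), dtype=np.float32)
    ch = 0
    from scipy.signal import hilbert  # local import keeps module load light

    for a, label in enumerate(config.labels):
        target = _aperiodic_psd(
            config.betas[a], config.aperiodic_amplitude, config.noise_floor, config.osc_peaks
        )
        gamma_on = label in config.gamma_array_set and env is not None
        for _ in range(config.channels_per_array):
            x = _shaped_noise(rng, n, fs, target)
            s = config.pac_strength
            needs_band = gamma_on or s > 0
            if needs_band:
                xb = bandpass_filter(x, fs, *config.gamma_band, order=4)
                amp_mod = np.ones(n)
                if gamma_on:
                    amp_mod *= np.sqrt(1.0 + (config.gamma_event_gain - 1.0) * env)
                if s > 0:
                    delta = _shaped_noise(
                        rng,
                        n,
                        fs,
                        _aperiodic_psd(
                            0.0,
                            0.0,
                            0.0,
                            [(config.pac_delta_hz, config.pac_delta_bw, 4 * target(config.pac_delta_hz))],
                        ),
                    )
                    phi = np.angle(hilbert(delta))
                    amp_mod *= (1.0 - s) + s * (1.0 + np.cos(phi)) / 2.0
                    x = x + delta
                x = x - xb + amp_mod * xb
            out[ch] = x
            ch += 1
    return out


# ---------------------------------------------------------------------------
# Spike trains


def _spikes_from_rate_grid(
    rate: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson train from a piecewise-constant rate grid."""
    counts = rng.poisson(np.maximum(rate, 0.0) * dt)
    total = counts.sum()
    if total == 0:
        return np.empty(0)
    bins = np.repeat(np.arange(rate.size), counts)
    times = (bins + rng.random(total)) * dt
    return np.sort(times)


def generate_spike_trains(
    config: SyntheticConfig,
    events: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], set[int]]:
    """Per-channel spike trains plus the planted responsive channel set.

    Responsive channels ramp up to ``pre_close_gain × baseline`` over the
    second before each closing onset and are suppressed for 0.5 s after;
    coordinated bursts (< 1 s) multiply the rate on a random channel subset
    at ``burst_rate_per_min``. Negative modulated rates are clipped to zero.
    """
    config.validate()
    if config.baseline_rate <= 0:
        raise ConfigError("baseline_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    dt = 0.01
    nt = int(round(config.duration_s / dt))
    t = np.arange(nt) * dt
    n_ch = config.n_channels
    labels = np.asarray(config.channel_array)
    pool = np.flatnonzero(np.isin(labels, config.labels[: min(2, config.n_arrays)]))
    n_resp = min(config.n_responsive, pool.size)
    responsive = set(int(i) for i in rng.choice(pool, size=n_resp, replace=False))

    close_onsets = (
        events.loc[events["event_type"] == "close", "onset_s"].to_numpy()
        if len(events)
        else np.array([])
    )
    resp_mod = np.ones(nt)
    for t0 in close_onsets:
        ramp = (t >= t0 - 1.0) & (t < t0)
        resp_mod[ramp] = np.maximum(
            resp_mod[ramp], 1.0 + (config.pre_close_gain - 1.0) * (t[ramp] - (t0 - 1.0))
        )
        post = (t >= t0) & (t < t0 + 0.5)
        resp_mod[post] = 0.3

    burst_windows: list[tuple[np.ndarray, np.ndarray]] = []
    if config.burst_rate_per_min > 0:
        n_bursts = rng.poisson(config.burst_rate_per_min * config.duration_s / 60.0)
        for _ in range(n_bursts):
            tb = rng.uniform(0, config.duration_s - config.burst_duration_s)
            members = rng.choice(
                n_ch, size=max(1, int(round(config.burst_channel_fraction * n_ch))), replace=False
            )
            mask = (t >= tb) & (t < tb + config.burst_duration_s)
            burst_windows.append((members, mask))

    spikes = []
    n_clipped = 0
    for c in range(n_ch):
        rate = np.full(nt, config.baseline_rate)
        if c in responsive:
            rate = rate * resp_mod
        for members, mask in burst_windows:
            if c in members:
                rate[mask] *= config.burst_gain
        n_clipped += int(np.sum(rate < 0))
        spikes.append(_spikes_from_rate_grid(rate, dt, rng))
    if n_clipped:
        log.warning("generate_spike_trains: %d rate samples clipped to 0", n_clipped)
    return spikes, responsive


# ---------------------------------------------------------------------------
# Center-out (Kinarm) sessions


def generate_kinarm_session(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, list[np.ndarray], np.ndarray, np.ndarray]:
    """Center-out movement table plus direction-tuned spike trains.

    Each row of the returned table is one movement (the out-and-back merging
    of opposite directions is a generator-side convention, so three trials
    per direction yield 24 movement rows). Tuned channels fire at
    ``baseline · movement_gain · (1 + tuning_depth·cos(θ − θ_pref))`` from
    0.3 s before target appearance until the target is reached.

    Returns ``(trials, spikes, preferred_direction, depth_per_channel)``;
    preferred directions are NaN for untuned channels.
    """
    config.validate()
    if config.n_trials_per_direction < 1:
        raise ConfigError("need at least one trial per direction")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    dirs = np.repeat(np.arange(8), config.n_trials_per_direction)
    dirs = rng.permutation(dirs)
    appear = 5.0 + np.arange(dirs.size) * config.trial_period_s
    reach = appear + rng.uniform(0.9, 1.1, dirs.size)
    trials = pd.DataFrame({"direction": dirs, "appear_s": appear, "reach_s": reach})
    duration = float(appear[-1] + config.trial_period_s + 5.0)

    n_ch = config.n_channels
    labels = np.asarray(config.channel_array)
    pool = np.flatnonzero(np.isin(labels, config.labels[: min(2, config.n_arrays)]))
    tuned = rng.choice(pool, size=min(config.n_tuned, pool.size), replace=False)
    pref = np.full(n_ch, np.nan)
    depth = np.zeros(n_ch)
    pref[tuned] = rng.uniform(0, 2 * np.pi, tuned.size)
    depth[tuned] = config.tuning_depth

    dt = 0.01
    nt = int(round(duration / dt))
    t = np.arange(nt) * dt
    spikes = []
    for c in range(n_ch):
        rate = np.full(nt, config.baseline_rate)
        if not np.isnan(pref[c]):
            for d, ta, tr_ in zip(dirs, appear, reach):
                theta = d * np.pi / 4
                win = (t >= ta - 0.3) & (t <= tr_)
                rate[win] = (
                    config.baseline_rate
                    * config.movement_gain
                    * (1.0 + depth[c] * np.cos(theta - pref[c]))
                )
        spikes.append(_spikes_from_rate_grid(rate, dt, rng))
    return trials, spikes, pref, depth


# ---------------------------------------------------------------------------
# Sync streams


def generate_sync_pair(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two copies of the shared pulse channel, the second delayed by
    ``stream_lag_s`` (positive = stream b lags stream a)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    fs = config.fs_lfp
    n = int(round(config.duration_s * fs))
    lag = int(round(config.stream_lag_s * fs))
    if abs(lag) >= n:
        raise ConfigError("stream lag exceeds the session duration")
    m = np.zeros(n + abs(lag))
    n_pulses = max(2, int(config.duration_s * config.sync_rate_hz))
    starts = np.sort(rng.uniform(0, (m.size - 1) / fs, n_pulses))
    width = int(round(0.02 * fs))
    for s0 in (starts * fs).astype(int):
        m[s0 : s0 + width] = 1.0
    m = m + rng.normal(0, 0.01, m.size)
    if lag >= 0:
        a, bstr = m[lag : lag + n], m[:n]
    else:
        a, bstr = m[: n], m[-lag : -lag + n]
    return a.copy(), bstr.copy(), config.stream_lag_s


# ---------------------------------------------------------------------------
# Whole sessions


def generate_arat_session(
    config: SyntheticConfig, include_lfp: bool = True
) -> tuple[SessionBundle, SyntheticGroundTruth]:
    """A full grasp-task session: aperture + events, LFP, spikes and sync.

    Deterministic: the same config (including its seed) reproduces the
    bundle bit for bit.
    """
    config.validate()
    rng_ap = np.random.default_rng(config.seed)
    aperture, events = generate_aperture_trace(config, rng_ap)
    lfp = (
        generate_lfp(config, events)
        if include_lfp
        else np.empty((0, 0), dtype=np.float32)
    )
    spikes, responsive = generate_spike_trains(config, events)
    sync_a, _, _ = generate_sync_pair(config)
    bundle = SessionBundle(
        lfp=lfp,
        fs_lfp=config.fs_lfp,
        channel_array=config.channel_array if include_lfp else config.channel_array,
        spikes=spikes,
        aperture=aperture,
        duration_s=config.duration_s,
        sync=sync_a,
        meta={"kind": "arat", "seed": config.seed},
    )
    truth = SyntheticGroundTruth(
        planted_events=events,
        responsive_channel_ids=responsive,
        true_beta_per_array=dict(zip(config.labels, config.betas)),
        true_pac_strength=config.pac_strength,
        stream_lag_s=config.stream_lag_s,
    )
    truth.validate(config.duration_s, config.n_channels)
    return bundle, truth


def generate_kinarm_bundle(
    config: SyntheticConfig, include_lfp: bool = False
) -> tuple[SessionBundle, SyntheticGroundTruth]:
    """A center-out session bundle with direction-tuned spikes (and,
    optionally, background LFP without event-locked gamma)."""
    config.validate()
    trials, spikes, pref, depth = generate_kinarm_session(config)
    duration = float(trials["reach_s"].iloc[-1] + 5.0)
    cfg2 = replace(config, duration_s=duration)
    lfp = (
        generate_lfp(cfg2, pd.DataFrame(columns=EVENT_COLUMNS))
        if include_lfp
        else np.empty((0, 0), dtype=np.float32)
    )
    sync_a, _, _ = generate_sync_pair(cfg2)
    bundle = SessionBundle(
        lfp=lfp,
        fs_lfp=config.fs_lfp,
        channel_array=config.channel_array,
        spikes=spikes,
        aperture=np.full(int(round(duration * APERTURE_FS)) + 1, 100.0),
        duration_s=duration,
        sync=sync_a,
        kinarm_trials=trials,
        meta={"kind": "kinarm", "seed": config.seed},
    )
    truth = SyntheticGroundTruth(
        planted_events=pd.DataFrame(columns=EVENT_COLUMNS),
        responsive_channel_ids=set(int(i) for i in np.flatnonzero(depth > 0)),
        true_beta_per_array=dict(zip(config.labels, config.betas)),
        true_pac_strength=0.0,
        preferred_direction=pref,
        tuning_depth=depth,
        stream_lag_s=config.stream_lag_s,
    )
    truth.validate(duration, config.n_channels)
    return bundle, truth
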