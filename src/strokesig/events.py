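"""Closing/opening event detection from the hand-aperture trace, and
event-aligned epoching.

Aperture is expressed as percent open (100 = fully open, 0 = fully closed),
sampled uniformly (20 samples/s in this study's kinematics). The validity
rules:

* **closing** — the hand starts from an at-least-80%-open position and the
  motion reaches fully closed (0%), with a relaxation admitting terminal
  apertures of at most 30%. If the motion pauses and resumes, the *latter*
  closing sweep that reaches the terminal aperture defines the event onset.
* **opening** — the mirror image: start at most 30% open, terminal aperture
  at least 80% (fully open canonical), onset at the latter qualifying sweep.

Motion is segmented into sweeps: maximal runs of per-sample change above a
noise deadband (default 1 %/sample) in one direction. A "hold" is a run of
at least two consecutive sub-deadband samples; a single quiet sample inside
an otherwise monotone sweep does not split it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "event_type",
    "onset_s",
    "end_s",
    "start_aperture",
    "end_aperture",
    "admitted_by",
]

CLOSE_START_MIN = 80.0  # % open required before a closing may begin
CLOSE_END_MAX = 30.0  # % open the terminal sweep must reach
FULL_TOL = 0.5  # % tolerance for calling an aperture "fully" open/closed


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def _sweeps(aperture: np.ndarray, deadband: float) -> list[tuple[int, int, int]]:
    """Maximal unidirectional runs as (start_idx, end_idx, direction).

    direction −1 = closing (aperture decreasing), +1 = opening. Indices are
    sample indices; a sweep spans aperture[start_idx] .. aperture[end_idx].
    """
    d = np.diff(aperture)
    step_dir = np.where(d <= -deadband, -1, np.where(d >= deadband, 1, 0))
    # a lone zero between two steps of the same sign belongs to that sweep
    for i in range(1, len(step_dir) - 1):
        if step_dir[i] == 0 and step_dir[i - 1] != 0 and step_dir[i - 1] == step_dir[i + 1]:
            step_dir[i] = step_dir[i - 1]
    sweeps = []
    i = 0
    n = len(step_dir)
    while i < n:
        if step_dir[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and step_dir[j + 1] == step_dir[i]:
            j += 1
        sweeps.append((i, j + 1, int(step_dir[i])))
        i = j + 1
    return sweeps


def _detect(
    aperture: np.ndarray,
    fs: float,
    deadband: float,
    direction: int,
) -> pd.DataFrame:
    """Shared detector; direction −1 finds closings, +1 openings."""
    ap = np.asarray(aperture, float)
    if ap.size and (ap.min() < -1e-6 or ap.max() > 100 + 1e-6):
        raise ValueError("aperture values must lie in [0, 100]")
    sweeps = _sweeps(ap, deadband)
    if direction == -1:
        start_ok = lambda a: a >= CLOSE_START_MIN
        end_ok = lambda a: a <= CLOSE_END_MAX
        full = lambda a: a <= FULL_TOL
        tags = ("reached_full_close", "reached_30pct_closed")
        etype = "close"
    else:
        start_ok = lambda a: a <= CLOSE_END_MAX
        end_ok = lambda a: a >= CLOSE_START_MIN
        full = lambda a: a >= 100 - FULL_TOL
        tags = ("reached_full_open", "reached_80pct_open")
        etype = "open"

    rows = []
    # episodes: consecutive same-direction sweeps with no opposite sweep between
    i = 0
    while i < len(sweeps):
        if sweeps[i][2] != direction:
            i += 1
            continue
        j = i
        while j + 1 < len(sweeps) and sweeps[j + 1][2] == direction:
            j += 1
        episode = sweeps[i : j + 1]
        start_ap = ap[episode[0][0]]
        qualifying = [s for s in episode if end_ok(ap[s[1]])]
        if start_ok(start_ap) and qualifying:
            final = qualifying[-1]  # the "latter" sweep that reached the target
            end_ap = ap[final[1]]
            rows.append(
                {
                    "event_type": etype,
                    "onset_s": final[0] / fs,
                    "end_s": final[1] / fs,
                    "start_aperture": start_ap,
                    "end_aperture": end_ap,
                    "admitted_by": tags[0] if full(end_ap) else tags[1],
                }
            )
        i = j + 1
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return table.sort_values("onset_s", ignore_index=True) if len(table) else table


def detect_closing_events(
    aperture: np.ndarray, fs: float = 20.0, deadband: float = 1.0
) -> pd.DataFrame:
    """Valid closing events (see module docstring for the rule)."""
    return _detect(aperture, fs, deadband, direction=-1)


def detect_opening_events(
    aperture: np.ndarray, fs: float = 20.0, deadband: float = 1.0
) -> pd.DataFrame:
    """Valid opening events — the mirror of the closing rule."""
    return _detect(aperture, fs, deadband, direction=+1)


def detect_events(aperture: np.ndarray, fs: float = 20.0, deadband: float = 1.0) -> pd.DataFrame:
    """Closing and opening events merged, sorted by onset."""
    both = pd.concat(
        [detect_closing_events(aperture, fs, deadband), detect_opening_events(aperture, fs, deadband)],
        ignore_index=True,
    )
    return both.sort_values("onset_s", ignore_index=True) if len(both) else both


# ---------------------------------------------------------------------------
# Epoching


def extract_continuous_epochs(
    x: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    pre_s: float = 1.0,
    post_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-aligned slices ``[onset − pre_s, onset + post_s)`` of a
    continuous recording (channels × samples).

    Returns ``(epochs, kept)`` where epochs is events × channels × samples
    and ``kept`` holds the indices of events whose epoch fit inside the
    record (out-of-bounds events are dropped and logged).
    """
    x = np.atleast_2d(np.asarray(x, float))
    n = x.shape[-1]
    wlen = int(round((pre_s + post_s) * fs))
    out, kept = [], []
    for i, t in enumerate(np.asarray(onsets, float)):
        s0 = int(round((t - pre_s) * fs))
        if s0 < 0 or s0 + wlen > n:
            log.warning("epoch at %.3f s exceeds record bounds; dropped", t)
            continue
        out.append(x[:, s0 : s0 + wlen])
        kept.append(i)
    return np.array(out), np.array(kept, int)


def extract_spike_epochs(
    spikes: list[np.ndarray],
    onsets: np.ndarray,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    duration_s: float | None = None,
) -> tuple[list[list[np.ndarray]], np.ndarray]:
    """Event-aligned spike times, re-referenced to each onset.

    Returns ``(epochs, kept)``: ``epochs[ch][ev]`` is the array of spike
    times in ``[−pre_s, post_s)`` relative to the event onset. Events whose
    window leaves ``[0, duration_s]`` are dropped and logged.
    """
    onsets = np.asarray(onsets, float)
    kept = []
    for i, t in enumerate(onsets):
        if t - pre_s < 0 or (duration_s is not None and t + post_s > duration_s):
            log.warning("epoch at %.3f s exceeds record bounds; dropped", t)
            continue
        kept.append(i)
    kept = np.array(kept, int)
    epochs = []
    for st in spikes:
        st = np.asarray(st, float)
        per_ev = []
        for i in kept:
            t = onsets[i]
            lo, hi = np.searchsorted(st, [t - pre_s, t + post_s])
            per_ev.append(st[lo:hi] - t)
        epochs.append(per_ev)
    return epochs, kept


def extract_epochs(data, events, pre_s: float = 1.0, post_s: float = 1.0, **kw):
    """Dispatch on data kind: ``(array, fs)`` tuple → continuous epochs,
    list of spike-time arrays → spike epochs. ``events`` may be an
    EventTable (uses its ``onset_s`` column) or a plain onset array.
    """
    onsets = events["onset_s"].to_numpy() if isinstance(events, pd.DataFrame) else events
    if isinstance(data, tuple):
        x, fs = data
        return extract_continuous_epochs(x, fs, onsets, pre_s, post_s, **kw)
    return extract_spike_epochs(data, onsets, pre_s, post_s, **kw)
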