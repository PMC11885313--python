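"""Session containers and HDF5 / JSON serialization.

A :class:`SessionBundle` holds everything recorded in one session: continuous
multichannel LFP with per-channel array labels, per-channel spike-time lists,
the hand-aperture trace (percent open, 20 samples/s), an optional center-out
trial table and the shared synchronization pulse channel.

HDF5 layout (written by :func:`save_session`, read by :func:`load_session`)::

    /lfp            float32, channels x samples; attrs: fs (Hz)
    /channel_array  fixed-length strings, array label per channel
    /spikes/ch{i:04d}  float64 spike times (s), strictly increasing
    /aperture       float64, percent open; attrs: fs (Hz)
    /sync           float32 pulse-train channel (at the LFP rate)
    /kinarm         optional group: direction, appear_s, reach_s columns
    root attrs      duration_s
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

APERTURE_FS = 20.0  # kinematics sampling rate, samples/s

KINARM_COLUMNS = ["direction", "appear_s", "reach_s"]


@dataclass
class SessionBundle:
    """One recording session.

    Attributes
    ----------
    lfp : (n_channels, n_samples) float array, volts. May be empty when a
        session was generated spikes-only.
    fs_lfp : LFP sampling rate, Hz.
    channel_array : array label (e.g. ``"L1"``) per channel.
    spikes : per-channel strictly increasing spike times, seconds.
    aperture : hand aperture, percent open (100 = fully open, 0 = fully
        closed), sampled at :data:`APERTURE_FS`.
    kinarm_trials : optional table of center-out movements with columns
        ``direction`` (0..7), ``appear_s``, ``reach_s``.
    sync : shared synchronization pulse channel at the LFP rate.
    duration_s : session length, seconds.
    """

    lfp: np.ndarray
    fs_lfp: float
    channel_array: list[str]
    spikes: list[np.ndarray]
    aperture: np.ndarray
    duration_s: float
    sync: np.ndarray | None = None
    kinarm_trials: pd.DataFrame | None = None
    fs_aperture: float = APERTURE_FS
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return max(len(self.spikes), self.lfp.shape[0] if self.lfp.size else 0)

    def validate(self) -> None:
        for i, st in enumerate(self.spikes):
            if len(st) > 1 and not np.all(np.diff(st) > 0):
                raise ValueError(f"spike times not strictly increasing on channel {i}")
        if self.aperture.size and (
            self.aperture.min() < -1e-9 or self.aperture.max() > 100 + 1e-9
        ):
            raise ValueError("aperture outside [0, 100]")
        if self.kinarm_trials is not None:
            t = self.kinarm_trials
            if not (t["appear_s"] < t["reach_s"]).all():
                raise ValueError("appearance time must precede reach time")

    def channels_of(self, array_label: str) -> np.ndarray:
        """Indices of the channels belonging to one array."""
        return np.flatnonzero(np.asarray(self.channel_array) == array_label)


def save_session(bundle: SessionBundle, path) -> None:
    bundle.validate()
    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = bundle.duration_s
        d = f.create_dataset("lfp", data=np.asarray(bundle.lfp, dtype=np.float32))
        d.attrs["fs"] = bundle.fs_lfp
        f.create_dataset(
            "channel_array",
            data=np.array(bundle.channel_array, dtype=h5py.string_dtype()),
        )
        g = f.create_group("spikes")
        for i, st in enumerate(bundle.spikes):
            g.create_dataset(f"ch{i:04d}", data=np.asarray(st, dtype=np.float64))
        a = f.create_dataset("aperture", data=np.asarray(bundle.aperture, np.float64))
        a.attrs["fs"] = bundle.fs_aperture
        if bundle.sync is not None:
            f.create_dataset("sync", data=np.asarray(bundle.sync, np.float32))
        if bundle.kinarm_trials is not None:
            k = f.create_group("kinarm")
            for col in KINARM_COLUMNS:
                k.create_dataset(col, data=bundle.kinarm_trials[col].to_numpy())


def load_session(path) -> SessionBundle:
    with h5py.File(path, "r") as f:
        lfp = f["lfp"][...]
        fs = float(f["lfp"].attrs["fs"])
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_array"][...]]
        keys = sorted(f["spikes"].keys())
        spikes = [f["spikes"][k][...] for k in keys]
        aperture = f["aperture"][...]
        fs_ap = float(f["aperture"].attrs["fs"])
        sync = f["sync"][...] if "sync" in f else None
        trials = None
        if "kinarm" in f:
            trials = pd.DataFrame({c: f["kinarm"][c][...] for c in KINARM_COLUMNS})
        return SessionBundle(
            lfp=lfp,
            fs_lfp=fs,
            channel_array=labels,
            spikes=spikes,
            aperture=aperture,
            duration_s=float(f.attrs["duration_s"]),
            sync=sync,
            kinarm_trials=trials,
            fs_aperture=fs_ap,
        )


def save_ground_truth(truth, path) -> None:
    """Serialize a SyntheticGroundTruth to JSON (events as records)."""
    payload = {
        "planted_events": truth.planted_events.to_dict(orient="records"),
        "responsive_channel_ids": sorted(int(i) for i in truth.responsive_channel_ids),
        "true_beta_per_array": {k: float(v) for k, v in truth.true_beta_per_array.items()},
        "true_pac_strength": float(truth.true_pac_strength),
        "preferred_direction": (
            None
            if truth.preferred_direction is None
            else [float(x) for x in truth.preferred_direction]
        ),
        "tuning_depth": (
            None if truth.tuning_depth is None else [float(x) for x in truth.tuning_depth]
        ),
        "stream_lag_s": float(truth.stream_lag_s),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
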