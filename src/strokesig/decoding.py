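"""Decoders: the training-less spectral threshold decoder for grasp, and the
eight-direction center-out population-decoding experiments with their
controls and metrics.

The threshold decoder is a two-state machine driven by the mean 100–500 Hz
spectral power averaged over selected channels: starting open, it issues a
*close* command when the feature exceeds an absolute threshold (10 V²/Hz in
the source study) and an *open* command when, while closed, the feature
returns to a baseline range ([0.5, 3] V²/Hz). Feature values between the
baseline range and the close threshold hold the current state (hysteresis),
so commands always alternate.

Direction decoding uses flattened NLIFR features (channels × time points
over a −0.5…+1 s segment around target appearance), a linear-kernel SVM or
kNN, repeated stratified random splits with two training samples per class,
and macro-averaged accuracy/precision/recall/specificity/F1. Controls:
label-shuffling permutation (chance = 1/K), random channel subsets, and the
all-channel variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .spikes import nlifr_from_spikes

log = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


# ---------------------------------------------------------------------------
# Training-less threshold decoder


@dataclass
class DecoderTrace:
    times: np.ndarray
    feature: np.ndarray  # mean spectral power, V²/Hz
    state: np.ndarray  # "open"/"closed" after each feature sample
    commands: list[tuple[float, str]]  # (time, "close"|"open"), alternating


def threshold_decoder(
    times: np.ndarray,
    feature: np.ndarray,
    close_thr: float = 10.0,
    open_lo: float = 0.5,
    open_hi: float = 3.0,
) -> DecoderTrace:
    """Run the hysteretic state machine over a feature series.

    Starting open: close when ``feature > close_thr``; open when, while
    closed, ``feature ∈ [open_lo, open_hi]``; otherwise hold state.
    """
    if open_hi >= close_thr:
        raise ValueError("open range upper edge must lie below the close threshold")
    times = np.asarray(times, float)
    feature = np.asarray(feature, float)
    state = np.empty(feature.size, dtype=object)
    commands: list[tuple[float, str]] = []
    closed = False
    for i, (t, v) in enumerate(zip(times, feature)):
        if not closed and v > close_thr:
            closed = True
            commands.append((float(t), "close"))
        elif closed and open_lo <= v <= open_hi:
            closed = False
            commands.append((float(t), "open"))
        state[i] = "closed" if closed else "open"
    return DecoderTrace(times=times, feature=feature, state=state, commands=commands)


# ---------------------------------------------------------------------------
# Direction dataset and classification


@dataclass
class FeatureMatrix:
    """NLIFR feature tensor with channel structure retained.

    ``features`` is samples × channels × time points (values in [0, 1]);
    classifiers consume the flattened samples × (channels·time) view.
    """

    features: np.ndarray
    labels: np.ndarray  # direction ∈ {0..7}
    channel_ids: np.ndarray
    times_rel: np.ndarray
    arm: str = ""

    @property
    def flat(self) -> np.ndarray:
        return self.features.reshape(self.features.shape[0], -1)

    def restrict_channels(self, subset: np.ndarray) -> "FeatureMatrix":
        """Restrict to positions (into this matrix's channel axis)."""
        subset = np.asarray(subset, int)
        return FeatureMatrix(
            features=self.features[:, subset, :],
            labels=self.labels,
            channel_ids=self.channel_ids[subset],
            times_rel=self.times_rel,
            arm=self.arm,
        )


def build_direction_dataset(
    trials: pd.DataFrame,
    spikes: list[np.ndarray],
    channel_set: np.ndarray | list[int],
    span: tuple[float, float] = (-0.5, 1.0),
    window_s: float = 0.3,
    step_s: float = 0.02,
    tau_s: float = 0.3,
    arm: str = "",
) -> FeatureMatrix:
    """One NLIFR feature sample per movement.

    ``trials`` needs ``direction`` (0..7, already merged so each row is one
    movement) and ``appear_s`` columns. Features are the NLIFR of the
    selected channels over ``span`` around target appearance (76 time points
    at the 20-ms default step). Directions with fewer than 2 movements are
    excluded with a warning (they cannot satisfy the 2-train split).
    """
    channel_set = np.asarray(channel_set, int)
    if channel_set.size == 0:
        raise ValueError("empty channel set")
    counts = trials["direction"].value_counts()
    bad = counts[counts < 2].index.tolist()
    if bad:
        log.warning("directions %s have < 2 movements; excluded", bad)
        trials = trials[~trials["direction"].isin(bad)]
    ch_spikes = [spikes[c] for c in channel_set]
    feats, labels = [], []
    for _, row in trials.iterrows():
        times_rel, nl = nlifr_from_spikes(
            ch_spikes, float(row["appear_s"]), span, window_s, step_s, tau_s
        )
        feats.append(nl)
        labels.append(int(row["direction"]))
    return FeatureMatrix(
        features=np.array(feats),
        labels=np.array(labels, int),
        channel_ids=channel_set,
        times_rel=times_rel,
        arm=arm,
    )


@dataclass
class ClassificationReport:
    model: str
    experiment: str
    n_iterations: int
    confusions: list[np.ndarray]
    metrics: dict[str, float]  # averages over iterations
    per_iteration: pd.DataFrame = field(repr=False, default=None)

    def to_row(self) -> dict:
        row = {"model": self.model, "experiment": self.experiment, "iterations": self.n_iterations}
        row.update(self.metrics)
        return row


def make_model(model: str, knn_k: int = 3, svm_c: float = 1.0):
    if model == "svm":
        return SVC(kernel="linear", C=svm_c)
    if model == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k)
    raise ValueError(f"unknown model {model!r}; expected 'svm' or 'knn'")


def metrics_from_confusion(conf: np.ndarray) -> dict[str, float]:
    """Overall accuracy and macro one-vs-rest precision/recall/specificity/F1.

    Per-class ratios with a zero denominator contribute 0 and are counted in
    the macro average.
    """
    conf = np.asarray(conf, float)
    if conf.size == 0 or conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be a non-empty square matrix")
    total = conf.sum()
    acc = np.trace(conf) / total
    k = conf.shape[0]
    prec = np.zeros(k)
    rec = np.zeros(k)
    spec = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        tn = total - tp - fp - fn
        prec[i] = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec[i] = tp / (tp + fn) if tp + fn > 0 else 0.0
        spec[i] = tn / (tn + fp) if tn + fp > 0 else 0.0
        f1[i] = 2 * prec[i] * rec[i] / (prec[i] + rec[i]) if prec[i] + rec[i] > 0 else 0.0
    return {
        "accuracy": float(acc),
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "specificity": float(spec.mean()),
        "f1": float(f1.mean()),
    }


def _stratified_split(labels: np.ndarray, n_train: int, rng: np.random.Generator):
    train_idx = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if members.size <= n_train:
            raise ValueError(f"class {cls} has <= {n_train} samples; cannot split")
        train_idx.extend(rng.choice(members, size=n_train, replace=False))
    train_idx = np.array(sorted(train_idx))
    test_idx = np.setdiff1d(np.arange(labels.size), train_idx)
    return train_idx, test_idx


def _run_iterations(
    X: np.ndarray,
    labels: np.ndarray,
    model: str,
    n_train_per_class: int,
    n_iter: int,
    rng: np.random.Generator,
    shuffle_labels: bool,
    experiment: str,
    knn_k: int = 3,
    svm_c: float = 1.0,
) -> ClassificationReport:
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    classes = np.unique(labels)
    confusions = []
    rows = []
    for _ in range(n_iter):
        y = rng.permutation(labels) if shuffle_labels else labels
        tr, te = _stratified_split(y, n_train_per_class, rng)
        clf = make_model(model, knn_k, svm_c)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        conf = confusion_matrix(y[te], pred, labels=classes)
        confusions.append(conf)
        rows.append(metrics_from_confusion(conf))
    per_iter = pd.DataFrame(rows)
    metrics = {k: float(per_iter[k].mean()) for k in METRIC_NAMES}
    return ClassificationReport(
        model=model,
        experiment=experiment,
        n_iterations=n_iter,
        confusions=confusions,
        metrics=metrics,
        per_iteration=per_iter,
    )


def classify_directions(
    fm: FeatureMatrix,
    model: str = "svm",
    n_train_per_class: int = 2,
    n_iter: int = 50,
    seed: int = 0,
    **model_kw,
) -> ClassificationReport:
    """Repeated stratified random splits: ``n_train_per_class`` samples per
    direction train the model, the rest are tested; metrics averaged over
    iterations."""
    rng = np.random.default_rng(seed)
    return _run_iterations(
        fm.flat, fm.labels, model, n_train_per_class, n_iter, rng, False, "original", **model_kw
    )


def permutation_control(
    fm: FeatureMatrix,
    model: str = "svm",
    n_train_per_class: int = 2,
    n_iter: int = 500,
    seed: int = 0,
    **model_kw,
) -> ClassificationReport:
    """Label-shuffling control: labels are permuted independently each
    iteration before the split–train–test cycle; mean accuracy should sit at
    the 1/K chance level."""
    rng = np.random.default_rng(seed)
    return _run_iterations(
        fm.flat, fm.labels, model, n_train_per_class, n_iter, rng, True, "shuffled", **model_kw
    )


def random_channel_control(
    fm_all: FeatureMatrix,
    model: str = "svm",
    n_sets: int = 100,
    set_size: int = 20,
    n_train_per_class: int = 2,
    n_iter: int = 50,
    seed: int = 0,
    **model_kw,
) -> tuple[list[ClassificationReport], dict[str, float]]:
    """Random channel-subset control: ``n_sets`` random subsets of
    ``set_size`` channels, each run through :func:`classify_directions`;
    returns the per-set reports and the mean metrics across sets."""
    n_ch = fm_all.features.shape[1]
    if set_size > n_ch:
        raise ValueError("set_size exceeds the available channel count")
    rng = np.random.default_rng(seed)
    reports = []
    for s in range(n_sets):
        subset = rng.choice(n_ch, size=set_size, replace=False)
        sub = fm_all.restrict_channels(np.sort(subset))
        rep = _run_iterations(
            sub.flat,
            sub.labels,
            model,
            n_train_per_class,
            n_iter,
            rng,
            False,
            f"random-channels-{s}",
            **model_kw,
        )
        reports.append(rep)
    mean_metrics = {
        k: float(np.mean([r.metrics[k] for r in reports])) for k in METRIC_NAMES
    }
    return reports, mean_metrics


def reports_to_table(reports: list[ClassificationReport]) -> pd.DataFrame:
    """Experiment × model summary table with the five metrics per row."""
    return pd.DataFrame([r.to_row() for r in reports])
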