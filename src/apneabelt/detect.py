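"""Per-minute SAHS classification and rule-based apnea event detection.

Covers four concerns:

* the LSTM-RNN minute classifier (three recurrent layers, dense head
  128/64/32/1, sigmoid output, binary cross-entropy) plus eight classical
  baselines fitted on summary features of the same minutes;
* the respiration-channel rule: a sustained collapse of the breathing
  envelope lasting at least 8 s is an apnea event;
* motion gating: minutes with large accelerometer variance are excluded
  from event counting;
* evaluation: confusion-matrix metrics (Se, Sp, +PV, Acc, F-score) and the
  apnea-hypopnea index (events per usable hour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import MinuteSegment
from .nn import LSTMClassifier
from .simgen import MotionTrace, RespirationTrace

__all__ = [
    "LSTMSpec", "TrainingBatch", "ConfusionSummary", "ApneaEvent",
    "bce_loss", "bce_grad", "bce_loss_single_term",
    "train_lstm", "predict_minutes", "train_baselines", "BASELINE_NAMES",
    "breathing_rule", "motion_gate", "compute_ahi", "evaluate",
    "stratified_split", "summary_features",
]

P_CLIP = 1e-7  # probability clipping for cross-entropy


@dataclass(frozen=True)
class LSTMSpec:
    """Architecture and training length of the minute classifier."""

    num_lstm_layers: int = 3
    lstm_hidden: int = 64
    dense_sizes: tuple[int, ...] = (128, 64, 32, 1)
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.dense_sizes[-1] != 1:
            raise ValueError("final dense size must be 1 (sigmoid output)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class TrainingBatch:
    """True labels Y and predicted probabilities P for a set of minutes."""

    Y: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        P = np.asarray(self.P, dtype=float)
        if Y.shape != P.shape:
            raise ValueError("Y and P must have matching shapes")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "P", np.clip(P, P_CLIP, 1.0 - P_CLIP))


@dataclass(frozen=True)
class ApneaEvent:
    start_s: float
    duration_s: float
    source: str = "breathing_rule"

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts plus the derived screening metrics.

    Undefined ratios (zero denominators) are reported as NaN, never as 0.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    Se: float = field(init=False)
    Sp: float = field(init=False)
    PPV: float = field(init=False)
    Acc: float = field(init=False)
    F: float = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num, den):
            return num / den if den > 0 else float("nan")

        se = ratio(self.TP, self.TP + self.FN)
        sp = ratio(self.TN, self.TN + self.FP)
        ppv = ratio(self.TP, self.TP + self.FP)
        acc = ratio(self.TP + self.TN, self.TP + self.TN + self.FP + self.FN)
        if np.isnan(se) or np.isnan(ppv) or se + ppv == 0:
            f = float("nan")
        else:
            f = 2 * se * ppv / (se + ppv)
        for name, val in (("Se", se), ("Sp", sp), ("PPV", ppv), ("Acc", acc),
                          ("F", f)):
            object.__setattr__(self, name, float(val))

    def as_dict(self) -> dict:
        return {"TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
                "Se": self.Se, "Sp": self.Sp, "PPV": self.PPV,
                "Acc": self.Acc, "F": self.F}


# ---------------------------------------------------------------------------
# loss


def bce_loss(batch: TrainingBatch) -> float:
    """Two-term binary cross-entropy, natural log, mean over the batch."""
    if batch.Y.size == 0:
        raise ValueError("empty batch")
    Y, P = batch.Y, batch.P
    return float(-np.mean(Y * np.log(P) + (1 - Y) * np.log(1 - P)))


def bce_grad(batch: TrainingBatch) -> np.ndarray:
    """dL/dP of :func:`bce_loss` (for gradient verification)."""
    Y, P = batch.Y, batch.P
    return (-Y / P + (1 - Y) / (1 - P)) / Y.size


def bce_loss_single_term(batch: TrainingBatch) -> float:
    """The one-term, base-10 form -sum_x Y_x lg(P_x).

    Kept only for loss-value comparison: it ignores negative minutes
    entirely, so it cannot train a binary sigmoid output and is not used by
    :func:`train_lstm`.
    """
    if batch.Y.size == 0:
        raise ValueError("empty batch")
    return float(-np.sum(batch.Y * np.log10(batch.P)))


# ---------------------------------------------------------------------------
# LSTM training


def _stack(segments: list[MinuteSegment]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.features for s in segments])
    y = np.array([s.label for s in segments], dtype=float)
    return X, y


def stratified_split(labels: np.ndarray, val_fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/validation index split."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(val_idx)))


def train_lstm(segments: list[MinuteSegment], spec: LSTMSpec = LSTMSpec(),
               seed: int = 0, val_fraction: float = 0.25
               ) -> tuple[LSTMClassifier, dict]:
    """Train the minute classifier; returns the model and a per-epoch log
    with train/validation loss and accuracy."""
    X, y = _stack(segments)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    tr, va = stratified_split(y, val_fraction, seed)
    model = LSTMClassifier(n_channels=X.shape[2],
                           num_lstm_layers=spec.num_lstm_layers,
                           lstm_hidden=spec.lstm_hidden,
                           dense_sizes=spec.dense_sizes, seed=seed)
    rng = np.random.default_rng(seed + 1)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]
    for _ in range(spec.epochs):
        order = rng.permutation(Xtr.shape[0])
        for start in range(0, order.size, spec.batch_size):
            sel = order[start:start + spec.batch_size]
            model.train_step(Xtr[sel], ytr[sel], lr=spec.learning_rate)
        tl, ta = model.evaluate(Xtr, ytr)
        vl, vaa = model.evaluate(Xva, yva)
        history["train_loss"].append(tl)
        history["train_acc"].append(ta)
        history["val_loss"].append(vl)
        history["val_acc"].append(vaa)
    history["train_idx"] = tr
    history["val_idx"] = va
    return model, history


def predict_minutes(model: LSTMClassifier,
                    segments: list[MinuteSegment]) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid probabilities and hard labels (threshold 0.5, ties -> 1)."""
    X, _ = _stack(segments)
    p = model.predict_proba(X)
    return p, (p >= 0.5).astype(np.int8)


# ---------------------------------------------------------------------------
# classical baselines

BASELINE_NAMES = ("SVM", "RFC", "DTC", "KNN", "ADAboosta", "GNB", "QDA", "BP")


def summary_features(segments: list[MinuteSegment], pool: int = 8) -> np.ndarray:
    """Fixed-length representation per minute: per-channel mean and sd plus
    the sequence mean-pooled to ``pool`` points per channel."""
    rows = []
    for s in segments:
        f = s.features
        n = f.shape[0] // pool * pool
        pooled = f[:n].reshape(pool, -1, f.shape[1]).mean(axis=1)
        rows.append(np.concatenate([f.mean(axis=0), f.std(axis=0),
                                    pooled.ravel()]))
    return np.asarray(rows)


def _make_baselines(seed: int) -> dict:
    return {
        "SVM": SVC(random_state=seed),
        "RFC": RandomForestClassifier(random_state=seed),
        "DTC": DecisionTreeClassifier(random_state=seed),
        "KNN": KNeighborsClassifier(),
        "ADAboosta": AdaBoostClassifier(random_state=seed),
        "GNB": GaussianNB(),
        # pooled-sequence features are collinear; QDA needs ridging to fit
        "QDA": QuadraticDiscriminantAnalysis(reg_param=1e-3),
        "BP": MLPClassifier(hidden_layer_sizes=(32,), max_iter=1000,
                            random_state=seed),
    }


def train_baselines(segments: list[MinuteSegment], seed: int = 0,
                    val_fraction: float = 0.25) -> dict[str, ConfusionSummary]:
    """Fit the eight classical classifiers on summary features of the same
    minutes, with the identical train/validation split as the LSTM, and
    return each method's validation confusion summary."""
    _, y = _stack(segments)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    F = summary_features(segments)
    tr, va = stratified_split(y, val_fraction, seed)
    out = {}
    for name, clf in _make_baselines(seed).items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(F[tr], y[tr])
            pred = clf.predict(F[va])
        out[name] = evaluate(pred.astype(int), y[va].astype(int))
    return out


# ---------------------------------------------------------------------------
# rule-based detection and gating


def breathing_rule(resp: RespirationTrace, threshold_s: float = 8.0,
                   window_s: float = 2.0, floor_frac: float = 0.2
                   ) -> list[ApneaEvent]:
    """Detect sustained breathing-envelope collapses.

    The envelope is the moving RMS of the (median-centred) belt signal over
    ``window_s`` windows; samples where it falls below ``floor_frac`` of the
    record's median envelope are abnormal. Because the RMS window smears a
    collapse edge inward by roughly half a window, each abnormal run is
    dilated by half a window per side before the duration test; maximal runs
    lasting at least ``threshold_s`` become apnea events.
    """
    fs = resp.fs
    if fs < 2:
        raise ValueError("breathing_rule requires fs >= 2 Hz")
    x = resp.samples - np.median(resp.samples)
    win = max(1, int(round(window_s * fs)))
    ms = uniform_filter1d(x ** 2, size=win, mode="nearest")
    env = np.sqrt(np.maximum(ms, 0.0))  # guard fp round-off below zero
    med = float(np.median(env))
    if med <= 0:
        warnings.warn("silent respiration channel: whole record flagged",
                      stacklevel=2)
        return [ApneaEvent(0.0, resp.samples.size / fs, source="breathing_rule")]
    mask = env < floor_frac * med
    events = []
    half = win // 2
    n = mask.size
    i = 0
    runs = []
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append([max(0, i - half), min(n, j + half)])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    for a, b in merged:
        dur = (b - a) / fs
        if dur >= threshold_s:
            events.append(ApneaEvent(start_s=a / fs, duration_s=dur,
                                     source="breathing_rule"))
    return events


def motion_gate(motion: MotionTrace, minutes: int,
                threshold_g: float = 0.02) -> np.ndarray:
    """Per-minute usability flags: a minute is unusable (False) when the
    standard deviation of the acceleration magnitude exceeds the threshold."""
    n_per_min = int(round(60 * motion.fs))
    if minutes * n_per_min > motion.x.size:
        raise ValueError("motion trace does not cover the requested minutes")
    mag = motion.magnitude
    mag = mag - np.median(mag)
    flags = np.empty(minutes, dtype=bool)
    for k in range(minutes):
        flags[k] = np.std(mag[k * n_per_min:(k + 1) * n_per_min]) <= threshold_g
    return flags


def _label_runs(labels: np.ndarray) -> int:
    labels = np.asarray(labels).astype(int)
    if labels.size == 0:
        return 0
    starts = np.flatnonzero(np.diff(np.concatenate([[0], labels])) == 1)
    return int(starts.size)


def compute_ahi(events_or_labels, usable_hours: float) -> float:
    """Apnea-hypopnea index: events per usable hour.

    Accepts either a list of events or a per-minute 0/1 label vector, in
    which case each maximal run of apneic minutes counts as one event.
    """
    if usable_hours <= 0:
        raise ValueError("usable_hours must be positive")
    if isinstance(events_or_labels, (list, tuple)):
        n_events = len(events_or_labels)
    else:
        n_events = _label_runs(events_or_labels)
    return n_events / usable_hours


def evaluate(predictions, truths) -> ConfusionSummary:
    """Confusion-matrix screening metrics from per-minute labels."""
    p = np.asarray(predictions).astype(int)
    t = np.asarray(truths).astype(int)
    if p.shape != t.shape:
        raise ValueError("predictions and truths must have equal length")
    return ConfusionSummary(
        TP=int(np.sum((p == 1) & (t == 1))),
        FP=int(np.sum((p == 1) & (t == 0))),
        TN=int(np.sum((p == 0) & (t == 0))),
        FN=int(np.sum((p == 0) & (t == 1))),
    )
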