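"""Sliding-window activity recognition over joint-angle streams.

Streams on the common grid are cut into 50%-overlap windows (0.1-2.0 s grid);
each window carries the modal activity and room label within it. Features per
channel are the mean and standard deviation of the angle and of its first and
second finite differences (scaled by the rate and rate squared), capturing
posture, movement speed, and movement change — 6 features per channel in a
fixed ordering.

Classification is evaluated subject-independently: leave-one-subject-out
folds, z-scoring fit on the training folds only, predictions pooled into one
confusion matrix. KNN uses Euclidean distance with deterministic tie-breaks
(equal distances -> lower training index first; tied vote -> the nearest
neighbor's label); the SVM is a one-vs-rest RBF machine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .taxonomy import ACTIVITIES, CHANNELS

WINDOW_GRID_S: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 21))
DEFAULT_WINDOW_S = 1.3
DEFAULT_KNN_K = 9
KNN_GRID = (5, 9, 49, 99)
FEATURES_PER_CHANNEL = 6


@dataclass(frozen=True)
class WindowSpec:
    length_s: float = DEFAULT_WINDOW_S
    overlap: float = 0.5
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("window length must be positive")
        if abs(self.overlap - 0.5) > 1e-12:
            raise ValueError("protocol fixes the window overlap at 50%")
        if self.n_samples < 2:
            raise ValueError("window must span at least 2 samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.length_s * self.rate_hz))

    @property
    def step(self) -> int:
        return max(1, self.n_samples // 2)


@dataclass
class LabeledWindowDataset:
    features: np.ndarray       # (n_windows, n_features)
    activity: np.ndarray       # (n_windows,) int codes into ACTIVITIES
    room: np.ndarray           # (n_windows,) str
    subject: np.ndarray        # (n_windows,) str
    start_s: np.ndarray        # (n_windows,)
    spec: WindowSpec

    def __len__(self) -> int:
        return self.features.shape[0]

    @staticmethod
    def concatenate(parts: list["LabeledWindowDataset"]) -> "LabeledWindowDataset":
        return LabeledWindowDataset(
            features=np.concatenate([p.features for p in parts]),
            activity=np.concatenate([p.activity for p in parts]),
            room=np.concatenate([p.room for p in parts]),
            subject=np.concatenate([p.subject for p in parts]),
            start_s=np.concatenate([p.start_s for p in parts]),
            spec=parts[0].spec,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.features, columns=[f"f{i:03d}" for i in range(self.features.shape[1])]
        )
        df.insert(0, "start_s", self.start_s)
        df.insert(1, "subject", self.subject)
        df.insert(2, "activity", np.asarray(ACTIVITIES, object)[self.activity])
        df.insert(3, "room", self.room)
        return df


def modal_label(labels: np.ndarray) -> object:
    """Majority label; an exact tie goes to the label whose run starts earlier."""
    values, first, counts = np.unique(labels, return_index=True, return_counts=True)
    top = counts == counts.max()
    cand_first = first[top]
    return values[top][np.argmin(cand_first)]


def extract_features(window: np.ndarray, rate_hz: float) -> np.ndarray:
    """Feature vector for one window: per channel mean/SD of the angle and of
    its first and second derivatives. ``window`` is (n_samples, n_channels)."""
    if window.shape[0] < 3:
        raise ValueError("need at least 3 samples for second derivatives")
    if np.isnan(window).any():
        raise ValueError("NaN in window; interpolate flagged samples upstream")
    d1 = np.diff(window, axis=0) * rate_hz
    d2 = np.diff(window, n=2, axis=0) * rate_hz**2
    feats = np.stack(
        [
            window.mean(axis=0),
            window.std(axis=0),
            d1.mean(axis=0),
            d1.std(axis=0),
            d2.mean(axis=0),
            d2.std(axis=0),
        ],
        axis=1,
    )  # (n_channels, 6)
    return feats.ravel()


def segment_windows(
    angles: np.ndarray,
    activity: np.ndarray,
    room: np.ndarray,
    subject_id: str,
    spec: WindowSpec,
    times: np.ndarray | None = None,
) -> LabeledWindowDataset:
    """Cut synchronized streams into labeled feature windows.

    Windows start every length/2; the trailing partial window is dropped.
    A stream shorter than one window yields an empty dataset with a warning.
    """
    n = angles.shape[0]
    w, step = spec.n_samples, spec.step
    t0 = 0.0 if times is None else float(times[0])
    if n < w:
        warnings.warn("stream shorter than one window; empty dataset")
        nf = angles.shape[1] * FEATURES_PER_CHANNEL
        return LabeledWindowDataset(
            np.empty((0, nf)), np.empty(0, int), np.empty(0, object),
            np.empty(0, object), np.empty(0), spec,
        )
    starts = np.arange(0, n - w + 1, step)
    sw = np.lib.stride_tricks.sliding_window_view(angles, w, axis=0)[starts]
    # sw: (n_win, n_channels, w) -> vectorized feature block
    d1 = np.diff(sw, axis=2) * spec.rate_hz
    d2 = np.diff(sw, n=2, axis=2) * spec.rate_hz**2
    feats = np.stack(
        [
            sw.mean(axis=2), sw.std(axis=2),
            d1.mean(axis=2), d1.std(axis=2),
            d2.mean(axis=2), d2.std(axis=2),
        ],
        axis=2,
    ).reshape(len(starts), -1)
    acts = np.array([modal_label(activity[s : s + w]) for s in starts])
    rooms = np.array([modal_label(room[s : s + w]) for s in starts], dtype=object)
    return LabeledWindowDataset(
        features=feats,
        activity=acts.astype(int),
        room=rooms,
        subject=np.full(len(starts), subject_id, dtype=object),
        start_s=t0 + starts / spec.rate_hz,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class _Scaler:
    """Center per feature; scale per feature *type* pooled over channels.

    All channels share units (degrees and their time derivatives), so the six
    feature families (mean, SD, d1 mean/SD, d2 mean/SD) are each standardized
    by one pooled scale. Per-feature z-scoring would instead inflate
    low-variance channels until between-subject style noise drowns large
    between-class angle differences.
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "_Scaler":
        nf = x.shape[1]
        sd = np.empty(nf)
        for t in range(FEATURES_PER_CHANNEL):
            idx = np.arange(t, nf, FEATURES_PER_CHANNEL)
            s = x[:, idx].std()
            sd[idx] = s if s > 0 else 1.0
        return cls(mean=x.mean(axis=0), sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


def knn_classify(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    k: int,
    chunk: int = 512,
) -> np.ndarray:
    """K-nearest-neighbor prediction with deterministic tie handling.

    Euclidean distance on z-scored features (scaler fit on train only).
    Neighbors are ordered by (distance, training index); a tied majority vote
    resolves to the nearest neighbor carrying a tied label.
    """
    if train_x.shape[0] == 0:
        raise ValueError("empty training set")
    if k > train_x.shape[0]:
        raise ValueError("k exceeds training-set size")
    scaler = _Scaler.fit(train_x)
    a = scaler.transform(train_x)
    b = scaler.transform(test_x)
    out = np.empty(b.shape[0], dtype=train_y.dtype)
    a_sq = np.einsum("ij,ij->i", a, a)
    for lo in range(0, b.shape[0], chunk):
        bb = b[lo : lo + chunk]
        d2 = a_sq[None, :] - 2.0 * (bb @ a.T) + np.einsum("ij,ij->i", bb, bb)[:, None]
        np.maximum(d2, 0.0, out=d2)
        if k < a.shape[0]:
            part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        else:
            part = np.broadcast_to(np.arange(a.shape[0]), (bb.shape[0], a.shape[0]))
        for i in range(bb.shape[0]):
            cand = part[i]
            order = cand[np.lexsort((cand, d2[i, cand]))]  # distance, then index
            labels = train_y[order]
            values, counts = np.unique(labels, return_counts=True)
            winners = set(values[counts == counts.max()])
            for lab in labels:  # nearest neighbor with a tied-majority label
                if lab in winners:
                    out[lo + i] = lab
                    break
    return out


def svm_rbf_classify(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    C: float = 10.0,
    gamma: float | str = "scale",
) -> np.ndarray:
    """One-vs-rest RBF support vector machine on z-scored features."""
    if train_x.shape[0] == 0:
        raise ValueError("empty training set")
    if C <= 0 or (isinstance(gamma, float) and gamma <= 0):
        raise ValueError("C and gamma must be positive")
    scaler = _Scaler.fit(train_x)
    model = OneVsRestClassifier(SVC(C=C, gamma=gamma, kernel="rbf", random_state=0))
    model.fit(scaler.transform(train_x), train_y)
    return model.predict(scaler.transform(test_x))


@dataclass
class ConfusionMatrix:
    """Pooled confusion over the 19-class taxonomy."""

    counts: np.ndarray  # (19, 19): rows = true, cols = predicted
    labels: tuple[str, ...] = ACTIVITIES

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        n = len(ACTIVITIES)
        counts = np.zeros((n, n), dtype=int)
        np.add.at(counts, (y_true.astype(int), y_pred.astype(int)), 1)
        return cls(counts=counts)

    @property
    def row_percent(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, 0.0)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts)) / max(1, self.counts.sum())

    def per_class_accuracy(self) -> np.ndarray:
        sums = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, np.diag(self.counts) / sums, np.nan)

    def largest_offdiagonal(self) -> tuple[str, str, float]:
        """(true class, predicted class, row %) of the biggest confusion."""
        pct = self.row_percent.copy()
        np.fill_diagonal(pct, -1.0)
        i, j = np.unravel_index(np.argmax(pct), pct.shape)
        return self.labels[i], self.labels[j], float(pct[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def _predict(model: dict, train_x, train_y, test_x) -> np.ndarray:
    kind = model.get("kind", "knn")
    if kind == "knn":
        return knn_classify(train_x, train_y, test_x, k=model.get("k", DEFAULT_KNN_K))
    if kind == "svm":
        return svm_rbf_classify(
            train_x, train_y, test_x,
            C=model.get("C", 10.0), gamma=model.get("gamma", "scale"),
        )
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class LosoResult:
    fold_subjects: list[str]
    fold_accuracy: list[float]
    confusion: ConfusionMatrix
    predictions: np.ndarray   # pooled, aligned with dataset order of test windows
    window_index: np.ndarray  # indices into the dataset for pooled predictions

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))


def loso_cv(dataset: LabeledWindowDataset, model: dict | None = None) -> LosoResult:
    """Leave-one-subject-out cross-validation with a pooled confusion matrix."""
    model = model or {"kind": "knn", "k": DEFAULT_KNN_K}
    subjects = sorted(set(dataset.subject))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    fold_subjects, fold_acc = [], []
    all_idx, all_pred = [], []
    for s in subjects:
        test = dataset.subject == s
        if not test.any():
            warnings.warn(f"subject {s} has no windows; fold skipped")
            continue
        train = ~test
        pred = _predict(model, dataset.features[train], dataset.activity[train],
                        dataset.features[test])
        fold_subjects.append(s)
        fold_acc.append(float(np.mean(pred == dataset.activity[test])))
        all_idx.append(np.nonzero(test)[0])
        all_pred.append(pred)
    idx = np.concatenate(all_idx)
    pred = np.concatenate(all_pred)
    conf = ConfusionMatrix.from_predictions(dataset.activity[idx], pred)
    return LosoResult(fold_subjects, fold_acc, conf, pred, idx)


def grid_evaluate(
    streams: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    window_lengths: tuple[float, ...] = WINDOW_GRID_S,
    knn_ks: tuple[int, ...] = KNN_GRID,
    include_svm: bool = True,
    rate_hz: float = 100.0,
) -> pd.DataFrame:
    """LOSO accuracy over the window-length x model grid.

    ``streams`` maps subject -> (angles, activity codes, rooms). Returns a
    table with one row per window length and one accuracy column per model;
    the attrs carry the argmax cell.
    """
    models = [(f"KNN{k}", {"kind": "knn", "k": k}) for k in knn_ks]
    if include_svm:
        models.append(("SVM", {"kind": "svm"}))
    rows = []
    for length in window_lengths:
        spec = WindowSpec(length_s=length, rate_hz=rate_hz)
        parts = [
            segment_windows(a, y, r, subj, spec)
            for subj, (a, y, r) in sorted(streams.items())
        ]
        ds = LabeledWindowDataset.concatenate(parts)
        row: dict[str, float] = {"window_s": length}
        for name, model in models:
            row[name] = loso_cv(ds, model).mean_accuracy
        rows.append(row)
    table = pd.DataFrame(rows).set_index("window_s")
    best_col = table.max().idxmax()
    best_row = table[best_col].idxmax()
    table.attrs["best"] = {"model": best_col, "window_s": float(best_row),
                           "accuracy": float(table.loc[best_row, best_col])}
    return table
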