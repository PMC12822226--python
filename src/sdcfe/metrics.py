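"""Nearest-centroid baseline and the evaluation surface.

Covers the confusion matrix (raw and row-normalized), binary
precision/recall/F1/accuracy, and the multi-class report: balanced
accuracy, macro-F1, the multiclass Matthews correlation coefficient
(covariance form over the confusion matrix), macro one-vs-rest AUC via the
rank (Mann–Whitney) statistic, and a macro expected calibration error with
10 equal-width probability bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import OmicsMatrix, ScalingStats
from .preprocessing import zscore_scale

N_ECE_BINS = 10


# ---------------------------------------------------------------------------
# nearest-centroid classifier
# ---------------------------------------------------------------------------

@dataclass
class CentroidModel:
    """Per-class mean profiles over z-scored training features."""

    centroids: pd.DataFrame  # (C, p), index = class labels in stored order
    classes: list[str]
    stats: ScalingStats


def centroid_fit(m: OmicsMatrix, y: pd.Series | np.ndarray) -> CentroidModel:
    """Fit class centroids as per-class means on z-scored features.

    The scaling statistics are learned on the training matrix and stored so
    test samples are standardized identically.
    """
    labels = pd.Series(np.asarray(y, dtype=object), index=m.values.index).astype(str)
    classes = sorted(labels.unique())
    counts = labels.value_counts()
    empty = [c for c in classes if counts.get(c, 0) < 1]
    if empty:
        raise ValueError(f"classes with no training samples: {empty}")
    scaled, stats = zscore_scale(m)
    centroids = scaled.values.groupby(labels, sort=True).mean().loc[classes]
    return CentroidModel(centroids=centroids, classes=classes, stats=stats)


def centroid_predict(model: CentroidModel, m: OmicsMatrix) -> pd.Series:
    """Assign each sample the class of the nearest centroid (Euclidean).

    Ties resolve to the first class in the model's stored order.
    """
    if set(m.feature_ids) != set(model.stats.feature_ids):
        raise ValueError("feature set does not match the fitted model")
    scaled, _ = zscore_scale(m, model.stats)
    X = scaled.values[model.centroids.columns].to_numpy()
    C = model.centroids.to_numpy()
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # argmin takes the first minimum -> tie rule
    pred = pd.Series(
        [model.classes[i] for i in idx], index=m.values.index, name="pred"
    )
    return pred


# ---------------------------------------------------------------------------
# confusion matrices and scalar metrics
# ---------------------------------------------------------------------------

def confusion(
    y_true, y_pred, classes: list[str] | None = None
) -> pd.DataFrame:
    """Count matrix with true classes as rows and predictions as columns."""
    yt = pd.Series(np.asarray(y_true, dtype=object)).astype(str)
    yp = pd.Series(np.asarray(y_pred, dtype=object)).astype(str)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(yt) | set(yp))
    unknown = (set(yt) | set(yp)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the declared class order: {sorted(unknown)}")
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(yt, yp):
        cm.loc[t, p] += 1
    return cm


def row_normalize(cm: pd.DataFrame) -> pd.DataFrame:
    """Normalize each row to sum to 1; all-zero rows stay 0 (with a warning)."""
    totals = cm.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(
            f"classes with zero true samples left unnormalized: "
            f"{list(totals.index[totals == 0])}",
            stacklevel=2,
        )
    safe = totals.replace(0, np.nan)
    return cm.div(safe, axis=0).fillna(0.0)


def basic_metrics(cm: pd.DataFrame, positive: str) -> dict[str, float]:
    """Binary precision, recall, F1 and accuracy (one-vs-rest reduction).

    Zero denominators yield 0 with a warning.
    """
    if positive not in cm.index:
        raise ValueError(f"unknown positive class {positive!r}")
    tp = float(cm.loc[positive, positive])
    fp = float(cm[positive].sum() - tp)
    fn = float(cm.loc[positive].sum() - tp)
    total = float(cm.to_numpy().sum())
    correct = float(np.trace(cm.to_numpy()))

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                          stacklevel=3)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = _ratio(correct, total, "accuracy")
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": accuracy,
    }


def mcc_from_confusion(cm: pd.DataFrame) -> float:
    """Multiclass Matthews correlation, covariance form over the counts."""
    C = cm.to_numpy(dtype=float)
    t = C.sum(axis=1)  # true-class totals
    p = C.sum(axis=0)  # predicted-class totals
    n = C.sum()
    cov_tp = np.trace(C) * n - t @ p
    cov_tt = n * n - t @ t
    cov_pp = n * n - p @ p
    denom = np.sqrt(cov_tt * cov_pp)
    if denom == 0:
        return 0.0
    return float(cov_tp / denom)


def auc_rank(scores: np.ndarray, positives: np.ndarray) -> float:
    """One-vs-rest AUC from the Mann–Whitney rank statistic, ties averaged."""
    pos = np.asarray(positives, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative samples")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def ece_binary(probs: np.ndarray, outcomes: np.ndarray, n_bins: int = N_ECE_BINS
               ) -> tuple[float, pd.DataFrame]:
    """Expected calibration error with equal-width bins, skipping empty bins.

    Returns the ECE and a per-bin calibration curve (midpoint, mean
    predicted probability, observed frequency, count).
    """
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1], right=False), 0, n_bins - 1)
    rows, ece = [], 0.0
    n = len(probs)
    for b in range(n_bins):
        mask = idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        conf = float(probs[mask].mean())
        acc = float(outcomes[mask].mean())
        ece += nb / n * abs(acc - conf)
        rows.append(
            {"bin_mid": float((edges[b] + edges[b + 1]) / 2),
             "mean_prob": conf, "observed_freq": acc, "count": nb}
        )
    return ece, pd.DataFrame(rows)


@dataclass
class MetricsReport:
    """Scalar metrics plus per-class detail and calibration curves."""

    accuracy: float
    balanced_accuracy: float
    macro_f1: float
    mcc: float
    macro_auc_ovr: float
    macro_ece: float
    per_class: pd.DataFrame  # precision/recall/f1 per class
    confusion: pd.DataFrame
    calibration: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
            "macro_auc_ovr": self.macro_auc_ovr,
            "macro_ece": self.macro_ece,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": {
                "classes": list(self.confusion.index),
                "counts": self.confusion.to_numpy().tolist(),
            },
        }


def multiclass_metrics(
    y_true,
    probs: pd.DataFrame,
    y_pred=None,
) -> MetricsReport:
    """Full multi-class report from labels and class-probability rows.

    ``probs`` has one column per class and rows summing to 1 (±1e-6).  When
    ``y_pred`` is omitted, predictions are the argmax class.  Classes absent
    from ``y_true`` are skipped in the macro AUC with a warning.
    """
    yt = pd.Series(np.asarray(y_true, dtype=object)).astype(str)
    P = probs.astype(float)
    sums = P.sum(axis=1).to_numpy()
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1 (±1e-6)")
    classes = [str(c) for c in P.columns]
    if y_pred is None:
        yp = pd.Series(P.to_numpy().argmax(axis=1)).map(lambda i: classes[i])
    else:
        yp = pd.Series(np.asarray(y_pred, dtype=object)).astype(str)
    cm = confusion(yt, yp, classes=classes)

    per_class = {}
    recalls, f1s = [], []
    for c in classes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bm = basic_metrics(cm, c)
        per_class[c] = {k: bm[k] for k in ("precision", "recall", "f1")}
        if cm.loc[c].sum() > 0:
            recalls.append(bm["recall"])
            f1s.append(bm["f1"])

    aucs, eces, curves = [], [], {}
    for c in classes:
        truth = (yt == c).to_numpy()
        p_c = P[c].to_numpy()
        ece_c, curve = ece_binary(p_c, truth)
        if truth.any() and (~truth).any():
            aucs.append(auc_rank(p_c, truth))
        else:
            warnings.warn(f"class {c!r} absent from y_true; skipped in macro AUC",
                          stacklevel=2)
        eces.append(ece_c)
        curves[c] = curve

    total = cm.to_numpy().sum()
    return MetricsReport(
        accuracy=float(np.trace(cm.to_numpy()) / total),
        balanced_accuracy=float(np.mean(recalls)) if recalls else 0.0,
        macro_f1=float(np.mean(f1s)) if f1s else 0.0,
        mcc=mcc_from_confusion(cm),
        macro_auc_ovr=float(np.mean(aucs)) if aucs else float("nan"),
        macro_ece=float(np.mean(eces)),
        per_class=pd.DataFrame(per_class).T,
        confusion=cm,
        calibration=curves,
    )
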