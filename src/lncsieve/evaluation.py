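"""Metric suite, stratified cross-validation, ROC/AUC and SVM-RFE.

The seven classification metrics — sensitivity, specificity, accuracy,
precision, F-measure, Matthews correlation coefficient and Cohen's
Kappa — are computed from a 2x2 confusion matrix with lncRNA as the
positive class.  Undefined denominators yield NaN (reported as "NA"),
never a silent 0, and NA folds are excluded from averages with a
warning.

Cross-validation is stratified with a seeded shuffle; transcripts with
identical base strings are grouped into the same fold so no duplicate
spans a train/test boundary.  Per fold, scaling and the SVM are fitted
on the training folds only.  The headline numbers are fold-averaged
metrics (pooled out-of-fold metrics are also reported).

Feature ranking follows the canonical SVM-RFE recipe: a linear-kernel
SVM is refitted while the features with the smallest squared weights
are iteratively discarded; the RBF model itself has no per-feature
weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from . import kmer
from .model import (
    DEFAULT_COST,
    DEFAULT_GAMMA,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    _coerce_features,
    _encode_labels,
    _fit_svm,
)
from .orf import Sequence

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "f_measure",
    "mcc",
    "kappa",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with lncRNA as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n

    @property
    def pr_a(self) -> float:
        """Observed agreement (accuracy)."""
        return (self.tp + self.tn) / self.total

    @property
    def pr_e(self) -> float:
        """Chance agreement expected from the marginals."""
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        return ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / self.total**2

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt, yp = _encode_labels(y_true), _encode_labels(y_pred)
        return cls(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            fp=int(((yt == -1) & (yp == 1)).sum()),
            tn=int(((yt == -1) & (yp == -1)).sum()),
            fn=int(((yt == 1) & (yp == -1)).sum()),
        )


@dataclass(frozen=True)
class MetricReport:
    """The seven-metric suite; undefined entries are NaN."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_measure: float
    mcc: float
    kappa: float

    def as_series(self) -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in METRIC_NAMES})


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """All seven metrics from one confusion matrix.

    MCC's denominator is sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); when any
    marginal is zero MCC is undefined (NaN).  Kappa is
    (Pr(a) − Pr(e)) / (1 − Pr(e)), undefined when Pr(e) = 1.
    """
    if cm.total < 1:
        raise ValueError("confusion matrix is empty")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    accuracy = (tp + tn) / cm.total
    precision = _ratio(tp, tp + fp)
    if math.isnan(sensitivity) or math.isnan(precision) or sensitivity + precision == 0:
        f_measure = math.nan
    else:
        f_measure = 2 * sensitivity * precision / (sensitivity + precision)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den > 0 else math.nan
    kappa = (cm.pr_a - cm.pr_e) / (1 - cm.pr_e) if cm.pr_e < 1 else math.nan
    return MetricReport(sensitivity, specificity, accuracy, precision, f_measure, mcc, kappa)


@dataclass(frozen=True)
class RocCurve:
    """ROC points from a decision-score threshold sweep, plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )

    def plot(self, ax=None):
        """Plot the curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, label=f"AUC = {self.auc:.4f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False-positive rate")
        ax.set_ylabel("True-positive rate")
        ax.legend(loc="lower right")
        return ax


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and trapezoidal AUC over decision scores.

    AUC equals the rank statistic: the probability that a random
    lncRNA outscores a random coding transcript, ties counted half.
    """
    y = _encode_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return RocCurve(fpr, tpr, thr, float(_sk_auc(fpr, tpr)))


class CVResults:
    """Outcome of one stratified k-fold cross-validation run."""

    def __init__(self, fold_metrics: pd.DataFrame, fold_cms: list[ConfusionMatrix],
                 oof: pd.DataFrame, folds: int, seed: int):
        self.fold_metrics = fold_metrics
        self.fold_cms = fold_cms
        self.oof = oof  # out-of-fold: id, label, score, fold
        self.folds = folds
        self.seed = seed
        self.pooled_cm = sum(fold_cms[1:], fold_cms[0])
        self.pooled_metrics = compute_metrics(self.pooled_cm).as_series()
        self.roc = roc_auc(oof["score"].to_numpy(), oof["label"].to_numpy())

    @property
    def mean_metrics(self) -> pd.Series:
        """Fold-averaged metrics (the default headline); NA folds excluded."""
        if self.fold_metrics[list(METRIC_NAMES)].isna().any().any():
            warnings.warn("undefined metrics in some folds were excluded from the mean")
        return self.fold_metrics[list(METRIC_NAMES)].mean(skipna=True)

    @property
    def auc(self) -> float:
        return self.roc.auc

    def report(self) -> pd.DataFrame:
        """Per-fold rows plus a mean row (the exportable TSV)."""
        mean_row = self.mean_metrics.to_frame().T
        mean_row.insert(0, "fold", "mean")
        table = pd.concat([self.fold_metrics, mean_row], ignore_index=True)
        return table

    def summary(self) -> str:
        lines = [
            f"Stratified {self.folds}-fold cross-validation (seed {self.seed})".center(58),
            "=" * 58,
            f"{'n (out-of-fold)':<24}{len(self.oof)}",
            f"{'Pooled confusion':<24}TP={self.pooled_cm.tp} FP={self.pooled_cm.fp} "
            f"TN={self.pooled_cm.tn} FN={self.pooled_cm.fn}",
            "-" * 58,
            f"{'metric':<14}{'fold mean':>12}{'pooled':>12}",
        ]
        means = self.mean_metrics
        for m in METRIC_NAMES:
            lines.append(f"{m:<14}{means[m]:>12.4f}{self.pooled_metrics[m]:>12.4f}")
        lines.append(f"{'AUC (pooled)':<14}{self.auc:>12.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)


def _duplicate_groups(keys: list[str]) -> np.ndarray | None:
    first: dict[str, int] = {}
    groups = np.empty(len(keys), dtype=int)
    for i, key in enumerate(keys):
        groups[i] = first.setdefault(key, i)
    return groups if len(first) < len(keys) else None


def cross_validate(
    data,
    labels,
    *,
    folds: int = 10,
    seed: int = 0,
    C: float | None = None,
    gamma: float | None = None,
    class_weight: str | None = None,
    grid_search: bool = False,
) -> CVResults:
    """Stratified k-fold CV of the full pipeline on labelled data.

    ``data`` may be a list of Sequence (featurized once up front) or a
    ready feature matrix.  Scaling and the SVM are refitted on the
    training folds of every split; reported metrics are fold averages,
    with pooled out-of-fold results alongside.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = _encode_labels(labels)
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], Sequence):
        ids = [s.id for s in data]
        keys = [s.bases for s in data]
        X = kmer.feature_frame(list(data)).to_numpy(dtype=float)
    else:
        X, ids = _coerce_features(data, None)
        ids = ids or [f"seq_{i}" for i in range(X.shape[0])]
        keys = [row.tobytes().hex() for row in X]
    class_sizes = {v: int((y == v).sum()) for v in (-1, 1)}
    if min(class_sizes.values()) < folds:
        raise ValueError(
            f"each class needs at least {folds} members, got {class_sizes}"
        )
    groups = _duplicate_groups(keys)
    if groups is None:
        splitter = StratifiedKFold(folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        splitter = StratifiedGroupKFold(folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y, groups)

    rows, cms, oof_parts = [], [], []
    for fold_no, (train_idx, test_idx) in enumerate(split_iter, start=1):
        results = _fit_svm(
            X[train_idx],
            y[train_idx],
            C=DEFAULT_COST if C is None else C,
            gamma=DEFAULT_GAMMA if gamma is None else gamma,
            class_weight=class_weight,
            seed=seed,
            grid_search=grid_search,
        )
        scores = results.decision_scores(X[test_idx])
        pred = np.where(scores > 0, 1, -1)
        cm = ConfusionMatrix.from_predictions(y[test_idx], pred)
        cms.append(cm)
        rows.append({"fold": fold_no, **compute_metrics(cm).as_series().to_dict()})
        oof_parts.append(
            pd.DataFrame(
                {
                    "id": [ids[i] for i in test_idx],
                    "label": np.where(
                        y[test_idx] == 1, POSITIVE_LABEL, NEGATIVE_LABEL
                    ),
                    "score": scores,
                    "fold": fold_no,
                }
            )
        )
    return CVResults(
        fold_metrics=pd.DataFrame(rows),
        fold_cms=cms,
        oof=pd.concat(oof_parts, ignore_index=True),
        folds=folds,
        seed=seed,
    )


def rank_features_rfe(
    data,
    labels,
    *,
    step: float = 0.1,
    C: float = 1.0,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """SVM-RFE feature ranking with a linear-kernel surrogate.

    At each round a linear SVM is fitted on the surviving (min-max
    scaled) features and the fraction ``step`` with the smallest
    squared weights is discarded (at least one per round).  Ties in
    squared weight are eliminated in ascending schema order.  The
    importance score of a feature is its squared weight at elimination
    time; rank 1 is the last survivor.
    """
    if not 0 < step <= 1:
        raise ValueError(f"step must be in (0, 1], got {step}")
    y = _encode_labels(labels)
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], Sequence):
        frame = kmer.feature_frame(list(data))
        X = frame.to_numpy(dtype=float)
        feature_names = list(frame.columns)
    else:
        X = np.asarray(
            data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else data,
            dtype=float,
        )
        if feature_names is None:
            if isinstance(data, pd.DataFrame):
                feature_names = list(data.columns)
            else:
                feature_names = [f"f{i}" for i in range(X.shape[1])]
    Xs = MinMaxScaler().fit_transform(X)
    n_features = Xs.shape[1]
    remaining = list(range(n_features))
    eliminated: list[tuple[int, float, int]] = []  # (feature, weight^2, round)
    round_no = 0
    while remaining:
        round_no += 1
        svm = SVC(kernel="linear", C=C).fit(Xs[:, remaining], y)
        w2 = np.asarray(svm.coef_).ravel() ** 2
        n_drop = max(1, int(math.floor(step * len(remaining))))
        order = np.argsort(w2, kind="stable")  # ties -> ascending schema order
        drop = order[: min(n_drop, len(remaining))]
        for local in drop:
            eliminated.append((remaining[local], float(w2[local]), round_no))
        keep = sorted(set(range(len(remaining))) - set(drop.tolist()))
        remaining = [remaining[i] for i in keep]
    table = pd.DataFrame(
        {
            "feature": [feature_names[i] for i, _, _ in eliminated],
            "importance": [w for _, w, _ in eliminated],
            "round": [r for _, _, r in eliminated],
        }
    )
    table["rank"] = np.arange(len(eliminated), 0, -1)
    table = table.sort_values("rank").reset_index(drop=True)
    return table[["rank", "feature", "importance", "round"]]
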