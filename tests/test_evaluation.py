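"""Metric suite, cross-validation, ROC and SVM-RFE ranking."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

import lncsieve as L


def metric_oracle(tp, fp, tn, fn):
    """Independent exact-arithmetic computation of the seven metrics."""
    total = tp + fp + tn + fn

    def frac(a, b):
        return float(Fraction(a, b)) if b else math.nan

    sens = frac(tp, tp + fn)
    spec = frac(tn, tn + fp)
    acc = frac(tp + tn, total)
    prec = frac(tp, tp + fp)
    if math.isnan(sens) or math.isnan(prec) or sens + prec == 0:
        f = math.nan
    else:
        f = 2 * sens * prec / (sens + prec)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else math.nan
    pr_a = Fraction(tp + tn, total)
    pr_e = Fraction((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp), total**2)
    kappa = float((pr_a - pr_e) / (1 - pr_e)) if pr_e != 1 else math.nan
    return sens, spec, acc, prec, f, mcc, kappa


def test_worked_confusion_matrix():
    report = L.compute_metrics(L.ConfusionMatrix(tp=90, fn=10, tn=80, fp=20))
    assert report.sensitivity == pytest.approx(0.90)
    assert report.specificity == pytest.approx(0.80)
    assert report.accuracy == pytest.approx(0.85)
    assert report.precision == pytest.approx(90 / 110)
    assert report.f_measure == pytest.approx(0.857142857, abs=1e-6)
    assert report.mcc == pytest.approx(0.70353, abs=1e-5)
    assert report.kappa == pytest.approx(0.70)  # Pr(a)=0.85, Pr(e)=0.5


def test_perfect_classifier_all_ones():
    report = L.compute_metrics(L.ConfusionMatrix(tp=30, fn=0, tn=50, fp=0))
    assert report.as_series().tolist() == [1] * 7


def test_chance_classifier_zero_mcc_and_kappa():
    report = L.compute_metrics(L.ConfusionMatrix(tp=25, fn=25, tn=25, fp=25))
    assert report.mcc == 0
    assert report.kappa == 0


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        L.ConfusionMatrix(tp=-1, fp=0, tn=0, fn=0)


def test_empty_matrix_rejected():
    with pytest.raises(ValueError, match="empty"):
        L.compute_metrics(L.ConfusionMatrix(0, 0, 0, 0))


def test_undefined_denominators_are_nan_not_zero():
    report = L.compute_metrics(L.ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
    assert math.isnan(report.precision)
    assert math.isnan(report.f_measure)
    assert math.isnan(report.mcc)
    assert report.specificity == 1.0


@given(
    st.tuples(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    ).filter(lambda t: sum(t) > 0)
)
def test_metrics_match_exact_arithmetic_oracle(counts):
    tp, fp, tn, fn = counts
    got = L.compute_metrics(L.ConfusionMatrix(tp, fp, tn, fn)).as_series().to_numpy()
    expected = np.array(metric_oracle(tp, fp, tn, fn))
    np.testing.assert_allclose(got, expected, atol=1e-12, equal_nan=True)


def test_mcc_and_kappa_cross_checked_against_sklearn():
    rng = np.random.default_rng(8)
    for _ in range(50):
        tp, fp, tn, fn = rng.integers(1, 60, size=4)
        y_true = [1] * (tp + fn) + [-1] * (tn + fp)
        y_pred = [1] * tp + [-1] * fn + [-1] * tn + [1] * fp
        report = L.compute_metrics(L.ConfusionMatrix(tp, fp, tn, fn))
        assert report.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-10)
        assert report.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-10)


# --- ROC -----------------------------------------------------------------


def rank_statistic(scores, labels):
    """Oracle: P(random positive outscores random negative), ties half."""
    pos = [s for s, l in zip(scores, labels) if l == "lncRNA"]
    neg = [s for s, l in zip(scores, labels) if l == "coding"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_perfect_separation():
    roc = L.roc_auc([3.0, 2.0, -1.0, -2.0], ["lncRNA", "lncRNA", "coding", "coding"])
    assert roc.auc == 1.0


def test_roc_all_ties():
    roc = L.roc_auc([0.5] * 6, ["lncRNA"] * 3 + ["coding"] * 3)
    assert roc.auc == 0.5


def test_roc_worked_example():
    roc = L.roc_auc([0.9, 0.8, 0.3], ["lncRNA", "coding", "lncRNA"])
    assert roc.auc == 0.5  # one win, one loss over the two pairs


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        L.roc_auc([1.0, 2.0], ["lncRNA", "lncRNA"])


def test_roc_monotone_and_matches_rank_statistic():
    rng = np.random.default_rng(21)
    for _ in range(30):
        n = int(rng.integers(4, 60))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = np.where(rng.random(n) < 0.5, "lncRNA", "coding")
        if len(set(labels)) < 2:
            continue
        roc = L.roc_auc(scores, labels)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.auc == pytest.approx(rank_statistic(scores, labels), abs=1e-12)


# --- Cross-validation ----------------------------------------------------


def test_cv_minimal_two_folds_two_per_class():
    rng = np.random.default_rng(0)
    X = rng.random((4, 1366))
    labels = ["lncRNA", "lncRNA", "coding", "coding"]
    cv = L.cross_validate(X, labels, folds=2, seed=0)
    for cm in cv.fold_cms:
        assert cm.p == 1 and cm.n == 1  # one example per class per fold
    assert len(cv.oof) == 4


def test_cv_too_many_folds_rejected():
    X = np.random.default_rng(0).random((6, 1366))
    with pytest.raises(ValueError, match="at least"):
        L.cross_validate(X, ["lncRNA"] * 3 + ["coding"] * 3, folds=4)


def test_cv_fold_conservation(small_labelled):
    seqs, labels = small_labelled
    cv = L.cross_validate(seqs, labels, folds=5, seed=3)
    pooled = sum(cv.fold_cms[1:], cv.fold_cms[0])
    oof_cm = L.ConfusionMatrix.from_predictions(
        cv.oof["label"], np.where(cv.oof["score"] > 0, 1, -1)
    )
    assert pooled == oof_cm == cv.pooled_cm
    assert len(cv.oof) == len(seqs)


def test_cv_duplicates_share_a_fold(small_labelled):
    seqs, labels = small_labelled
    # plant three copies of one lncRNA under fresh ids
    dup = seqs[0]
    extra = [L.Sequence(f"dup_{i}", dup.bases) for i in range(2)]
    cv = L.cross_validate(
        seqs + extra, list(labels) + ["lncRNA"] * 2, folds=5, seed=3
    )
    folds = cv.oof.set_index("id").loc[[dup.id, "dup_0", "dup_1"], "fold"]
    assert folds.nunique() == 1


def test_cv_permuted_labels_sit_at_chance(small_features):
    X, labels = small_features
    rng = np.random.default_rng(12)
    permuted = rng.permutation(labels)
    cv = L.cross_validate(X, permuted, folds=5, seed=4)
    assert 0.3 <= cv.mean_metrics["accuracy"] <= 0.7


def test_cv_report_has_mean_row(small_labelled):
    seqs, labels = small_labelled
    cv = L.cross_validate(seqs, labels, folds=5, seed=3)
    report = cv.report()
    assert list(report["fold"])[-1] == "mean"
    assert len(report) == 6
    mean_row = report.iloc[-1]
    assert mean_row["accuracy"] == pytest.approx(cv.mean_metrics["accuracy"])


# --- SVM-RFE -------------------------------------------------------------


def test_rfe_recovers_planted_signal():
    rng = np.random.default_rng(7)
    n = 80
    X = rng.normal(size=(n, 8))
    y = np.where(rng.random(n) < 0.5, 1, -1)
    X[:, 3] += 3.0 * y  # only feature 3 is informative
    ranking = L.rank_features_rfe(X, y, step=0.25)
    assert ranking.iloc[0]["feature"] == "f3"
    assert ranking.iloc[0]["rank"] == 1


def test_rfe_duplicated_features_get_adjacent_ranks():
    rng = np.random.default_rng(9)
    n = 60
    X = rng.normal(size=(n, 6))
    y = np.where(rng.random(n) < 0.5, 1, -1)
    X[:, 0] += 1.5 * y
    X[:, 1] = X[:, 0]  # exact duplicate
    ranking = L.rank_features_rfe(X, y, step=1 / 6).set_index("feature")
    assert abs(int(ranking.loc["f0", "rank"]) - int(ranking.loc["f1", "rank"])) == 1


def test_rfe_ranking_covers_all_features(small_features):
    X, labels = small_features
    keep = np.r_[0:20, 60:80]  # 20 per class
    sub = X.iloc[keep, :50]
    ranking = L.rank_features_rfe(
        np.asarray(sub), np.asarray(labels)[keep], step=0.5,
        feature_names=list(sub.columns),
    )
    assert len(ranking) == 50
    assert sorted(ranking["rank"]) == list(range(1, 51))
    assert set(ranking["feature"]) == set(sub.columns)


@pytest.mark.parametrize("step", [0, -0.5, 1.5])
def test_rfe_step_out_of_range(step):
    with pytest.raises(ValueError, match="step"):
        L.rank_features_rfe(np.zeros((4, 3)), [1, 1, -1, -1], step=step)


def test_rfe_on_pipeline_features_puts_orf_features_on_top():
    cfg = L.GeneratorConfig(
        n_per_class=40,
        seed=5,
        coding_base_weights=(0.25, 0.25, 0.25, 0.25),
        noncoding_base_weights=(0.25, 0.25, 0.25, 0.25),
    )
    coding, noncoding = L.generate_dataset(cfg)
    seqs = noncoding + coding
    labels = ["lncRNA"] * 40 + ["coding"] * 40
    ranking = L.rank_features_rfe(seqs, labels, step=0.2)
    top = set(ranking.head(2)["feature"])
    assert top & {"orf_length", "orf_coverage"}
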