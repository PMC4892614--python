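"""ROC/AUC, optimal operating point, McNemar, splits."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from fuzzystage.evaluation import (ConfusionCounts, auc_ci_bootstrap,
                                   confusion, evaluate_model, mcnemar,
                                   optimal_point, roc_curve, sensitivity,
                                   specificity, split_cohort)


def mann_whitney_auc(scores, labels):
    """Tie-adjusted pair-counting AUC as an exact rational."""
    pos = [s for s, l in zip(scores, labels) if l == 2]
    neg = [s for s, l in zip(scores, labels) if l == 1]
    total = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                total += 1
            elif p == n:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


# ----------------------------------------------------------------- split

def test_split_sizes_published_protocol():
    train, val = split_cohort(list(range(399)), seed=0)
    assert (len(train), len(val)) == (266, 133)
    assert sorted(train + val) == list(range(399))


def test_split_deterministic_and_degenerate():
    a = split_cohort(list(range(50)), seed=3)
    b = split_cohort(list(range(50)), seed=3)
    assert a == b
    with pytest.raises(ValueError):
        split_cohort(list(range(10)), train_fraction=1.0)
    with pytest.raises(ValueError):
        split_cohort([1])


def test_split_stratified_preserves_class_ratio():
    labels = [1] * 90 + [2] * 110
    train, val = split_cohort(list(range(200)), seed=1, stratified=True,
                              labels=labels)
    train_ed = sum(labels[i] == 2 for i in train)
    assert train_ed == round(110 * 2 / 3)
    assert len(train) + len(val) == 200


# ------------------------------------------------------------- confusion

def test_confusion_hand_count():
    c = confusion(["ED", "ED", "OCD", "OCD"], ["ED", "OCD", "OCD", "ED"])
    assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)
    assert c.p == 2 and c.n == 2


def test_confusion_numeric_labels_and_errors():
    c = confusion([2, 2, 1], [2, 1, 1])
    assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 0)
    with pytest.raises(ValueError):
        confusion([], [])
    with pytest.raises(ValueError):
        confusion([2, 1], [2])
    with pytest.raises(ValueError):
        confusion(["ED", "bad"], ["ED", "ED"])


@pytest.mark.parametrize("tp,fn,expected", [(5, 0, 1.0), (0, 5, 0.0), (3, 1, 0.75)])
def test_sensitivity_values(tp, fn, expected):
    assert sensitivity(ConfusionCounts(tp, 0, 0, fn)) == expected


@pytest.mark.parametrize("tn,fp,expected", [(5, 0, 1.0), (0, 5, 0.0), (1, 3, 0.25)])
def test_specificity_values(tn, fp, expected):
    assert specificity(ConfusionCounts(0, fp, tn, 0)) == expected


def test_rates_undefined_without_class():
    with pytest.raises(ValueError):
        sensitivity(ConfusionCounts(0, 1, 1, 0))
    with pytest.raises(ValueError):
        specificity(ConfusionCounts(1, 0, 0, 1))


# ------------------------------------------------------------------- ROC

def test_roc_perfect_classifier():
    roc = roc_curve([0.9, 0.8, 0.1, 0.2], [2, 2, 1, 1])
    assert roc.auc == pytest.approx(1.0)
    assert roc.optimal[:2] == (0.0, 1.0)


def test_roc_uninformative_scores():
    roc = roc_curve([0.5] * 6, [2, 2, 2, 1, 1, 1])
    assert roc.auc == pytest.approx(0.5)
    assert list(roc.fpr) == [0.0, 1.0] and list(roc.tpr) == [0.0, 1.0]
    assert roc.optimal[:2] == (0.0, 0.0)   # tie-break toward smaller FPR


def test_roc_mixed_instance_exact_auc():
    scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
    labels = [2, 2, 2, 1, 1, 1]
    roc = roc_curve(scores, labels)
    assert roc.auc == pytest.approx(8 / 9)
    # optimal point by exhaustive Youden with the low-FPR tie-break
    assert roc.optimal[0] == pytest.approx(0.0)
    assert roc.optimal[1] == pytest.approx(2 / 3)


def test_roc_endpoints_and_monotone():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=40)
    labels = np.where(rng.random(40) < 0.5, 2, 1)
    if len(set(labels)) < 2:
        labels[0], labels[1] = 1, 2
    roc = roc_curve(scores, labels)
    assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
    assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)


def test_trapezoid_auc_equals_mann_whitney_on_random_instances():
    rng = np.random.default_rng(4)
    for _ in range(20):
        n = int(rng.integers(4, 15))
        scores = rng.integers(0, 5, size=n).astype(float)  # force ties
        labels = np.where(rng.random(n) < 0.5, 2, 1)
        if len(set(labels)) < 2:
            continue
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(float(mann_whitney_auc(scores, labels)),
                                        abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=30)
    labels = np.array([2, 1] * 15)
    a1 = roc_curve(scores, labels).auc
    a2 = roc_curve(np.exp(scores), labels).auc
    a3 = roc_curve(np.clip(scores - 1.0, -0.5, None), labels).auc
    assert a1 == pytest.approx(a2)
    # clipping is only weakly monotone; AUC may differ, but exp must not
    assert a3 <= 1.0


def test_relabelling_flips_auc():
    rng = np.random.default_rng(6)
    scores = rng.normal(size=25)
    labels = np.where(rng.random(25) < 0.4, 2, 1)
    labels[:2] = [1, 2]
    a = roc_curve(scores, labels).auc
    b = roc_curve(scores, 3 - labels).auc
    assert a + b == pytest.approx(1.0)


def test_roc_one_class_rejected():
    with pytest.raises(ValueError):
        roc_curve([0.1, 0.2], [2, 2])


# --------------------------------------------------------------- McNemar

def test_mcnemar_identical_predictions():
    stat, p, (b, c) = mcnemar([2, 1, 2, 1], [2, 1, 2, 1])
    assert (stat, p, b, c) == (0.0, 1.0, 0, 0)


def test_mcnemar_balanced_discordance_p_one():
    # b = c = 2 -> statistic 0, p = 1 (the published p = 1.000 pattern)
    truth = [2, 2, 1, 1, 2, 1]
    pred = [1, 1, 2, 2, 2, 1]
    stat, p, (b, c) = mcnemar(truth, pred)
    assert b == c == 2
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_mcnemar_chi2_oracle():
    # b = 10, c = 2: chi2 = 64/12, p from the chi-square distribution
    truth = [2] * 10 + [1] * 2 + [2, 1] * 5
    pred = [1] * 10 + [2] * 2 + [2, 1] * 5
    stat, p, (b, c) = mcnemar(truth, pred)
    assert (b, c) == (10, 2)
    assert stat == pytest.approx(64 / 12)
    assert p == pytest.approx(float(sps.chi2.sf(64 / 12, 1)), rel=1e-12)
    assert p == pytest.approx(0.0209, abs=2e-4)


def test_mcnemar_exact_binomial():
    truth = [2] * 5 + [1] * 1
    pred = [1] * 5 + [2] * 1
    _, p, (b, c) = mcnemar(truth, pred, method="exact")
    assert (b, c) == (5, 1)
    assert p == pytest.approx(float(sps.binomtest(5, 6, 0.5).pvalue))
    with pytest.raises(ValueError):
        mcnemar(truth, pred, method="nope")


# --------------------------------------------------------------- reports

def test_evaluate_model_perfect_scores():
    rep = evaluate_model([0.9, 0.8, 0.2, 0.1], [2, 2, 1, 1])
    assert rep.auc == pytest.approx(1.0)
    assert (rep.optimal_fpr, rep.optimal_tpr) == (0.0, 1.0)
    assert rep.mcnemar_p == pytest.approx(1.0)


def test_evaluate_model_self_consistent():
    rng = np.random.default_rng(8)
    scores = rng.normal(size=60)
    labels = np.where(rng.random(60) < 0.5, 2, 1)
    labels[:2] = [1, 2]
    rep = evaluate_model(scores, labels)
    pred = np.where(scores >= rep.optimal_threshold, 2, 1)
    counts = confusion(labels, pred)
    assert rep.optimal_tpr == pytest.approx(sensitivity(counts))
    assert rep.optimal_fpr == pytest.approx(1.0 - specificity(counts))
    assert rep.sensitivity == pytest.approx(rep.optimal_tpr)


def test_evaluate_model_report_deterministic():
    scores = [0.9, 0.3, 0.8, 0.2, 0.5, 0.6]
    labels = [2, 1, 2, 1, 1, 2]
    r1 = evaluate_model(scores, labels).to_json()
    r2 = evaluate_model(scores, labels).to_json()
    assert r1 == r2


def test_auc_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(10)
    scores = np.concatenate([rng.normal(1.0, 1.0, 40), rng.normal(0.0, 1.0, 40)])
    labels = np.array([2] * 40 + [1] * 40)
    auc = roc_curve(scores, labels).auc
    lo, hi = auc_ci_bootstrap(scores, labels, n_boot=200, seed=0)
    assert lo <= auc <= hi


def test_cross_check_against_sklearn():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(11)
    scores = rng.normal(size=80)
    labels = np.where(rng.random(80) < 0.45, 2, 1)
    labels[:2] = [1, 2]
    assert roc_curve(scores, labels).auc == pytest.approx(
        roc_auc_score(labels == 2, scores))
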