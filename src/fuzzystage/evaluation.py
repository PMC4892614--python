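"""Binary-classifier evaluation for the staging comparison.

Extra-prostatic disease (ED) is always the positive class.  Provides the
confusion counts, sensitivity/specificity, the ROC curve with trapezoidal
AUC and the Youden-optimal operating point, McNemar's paired test on
predictions vs truth, the 2/3-1/3 train/validation split protocol, and a
bundled per-model report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ConfusionCounts", "ROCAnalysis", "ModelReport", "split_cohort",
           "confusion", "sensitivity", "specificity", "roc_curve",
           "optimal_point", "mcnemar", "evaluate_model", "auc_ci_bootstrap"]


def _as_positive_mask(labels) -> np.ndarray:
    """Normalise OCD/ED or 1/2 labels to a boolean ED (positive) mask."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty label sequence")
    if arr.dtype.kind in "UO":
        vals = set(map(str, arr.tolist()))
        if not vals <= {"OCD", "ED"}:
            raise ValueError(f"labels must be 'OCD'/'ED', got {sorted(vals)}")
        return np.array([str(v) == "ED" for v in arr.tolist()])
    vals = set(np.unique(arr).tolist())
    if not vals <= {1, 2, 1.0, 2.0}:
        raise ValueError(f"numeric labels must be 1 (OCD) / 2 (ED), got {sorted(vals)}")
    return np.asarray(arr, float) == 2.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn


@dataclass
class ROCAnalysis:
    thresholds: np.ndarray    # descending cutoffs, one per curve point
    fpr: np.ndarray           # starts at 0, ends at 1
    tpr: np.ndarray
    auc: float
    optimal: tuple            # (fpr, tpr, threshold)


def split_cohort(records: Sequence, train_fraction: float = 2.0 / 3.0,
                 seed: int = 0, stratified: bool = False,
                 labels: Optional[Sequence] = None):
    """Seeded random partition into (train, validation).

    The training size is ``round(n * train_fraction)`` (266/133 for n=399
    at 2/3).  With ``stratified=True`` the class ratio is preserved per
    subset, using ``labels`` or each record's ``pt_group``.
    """
    records = list(records)
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(round(n * train_fraction))
    if n_train <= 0 or n_train >= n:
        raise ValueError(f"train_fraction={train_fraction} leaves an empty subset")
    rng = np.random.default_rng(seed)
    if not stratified:
        idx = rng.permutation(n)
        train_idx, val_idx = idx[:n_train], idx[n_train:]
    else:
        if labels is None:
            labels = [getattr(r, "pt_group", None) for r in records]
        lab = np.asarray(labels)
        train_parts, val_parts = [], []
        for cls in np.unique(lab):
            cls_idx = np.flatnonzero(lab == cls)
            if cls_idx.size == 0:
                raise ValueError(f"empty class {cls} under stratification")
            k = int(round(cls_idx.size * train_fraction))
            perm = rng.permutation(cls_idx)
            train_parts.append(perm[:k])
            val_parts.append(perm[k:])
        train_idx = np.concatenate(train_parts)
        val_idx = np.concatenate(val_parts)
        if train_idx.size == 0 or val_idx.size == 0:
            raise ValueError("stratified split left an empty subset")
    return [records[i] for i in train_idx], [records[i] for i in val_idx]


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Confusion counts with ED as the positive class."""
    t = _as_positive_mask(true_labels)
    p = _as_positive_mask(predicted_labels)
    if t.size != p.size:
        raise ValueError("label sequences must have equal length")
    return ConfusionCounts(tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
                           tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)))


def sensitivity(counts: ConfusionCounts) -> float:
    """True positive rate tp / (tp + fn)."""
    if counts.p == 0:
        raise ValueError("sensitivity undefined: no positive records")
    return counts.tp / counts.p


def specificity(counts: ConfusionCounts) -> float:
    """True negative rate tn / (tn + fp)."""
    if counts.n == 0:
        raise ValueError("specificity undefined: no negative records")
    return counts.tn / counts.n


def roc_curve(scores, true_labels) -> ROCAnalysis:
    """ROC curve sweeping a cutoff over every distinct score (ties grouped).

    A record is called positive when its score is >= the cutoff, so the
    curve runs from (0, 0) at cutoff +inf to (1, 1) at the minimum score.
    AUC is the trapezoidal integral; the optimal operating point maximises
    Youden's J (ties toward the smaller FPR).
    """
    s = np.asarray(scores, float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    pos = _as_positive_mask(true_labels)
    if pos.size != s.size:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis needs both classes present")

    cuts = np.unique(s)[::-1]                         # descending
    thresholds = np.concatenate(([np.inf], cuts))
    # cumulative positives/negatives with score >= cut
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    tp_cum = np.cumsum(pos_sorted)
    fp_cum = np.cumsum(~pos_sorted)
    # index of last record with score >= each cut
    last = s.size - 1 - np.searchsorted(s_sorted[::-1], cuts, side="left")
    tpr = np.concatenate(([0.0], tp_cum[last] / n_pos))
    fpr = np.concatenate(([0.0], fp_cum[last] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    roc = ROCAnalysis(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
                      optimal=(np.nan, np.nan, np.nan))
    roc.optimal = optimal_point(roc)
    return roc


def optimal_point(roc: ROCAnalysis) -> tuple:
    """The curve point maximising Youden's J = TPR - FPR (ties: lower FPR)."""
    j = roc.tpr - roc.fpr
    candidates = np.flatnonzero(j >= j.max() - 1e-12)
    best = candidates[np.argmin(roc.fpr[candidates])]
    return (float(roc.fpr[best]), float(roc.tpr[best]),
            float(roc.thresholds[best]))


def mcnemar(true_labels, predicted_labels, method: str = "chi2"):
    """McNemar's paired test of predictions against the true outcomes.

    Discordant counts are b = false negatives and c = false positives.
    ``chi2``: statistic (b - c)^2 / (b + c) without continuity correction,
    p from the chi-square distribution with 1 df (b + c = 0 gives p = 1).
    ``exact``: two-sided binomial(b; b + c, 1/2).
    Returns ``(statistic, p_value, (b, c))``.
    """
    counts = confusion(true_labels, predicted_labels)
    b, c = counts.fn, counts.fp
    if method == "chi2":
        if b + c == 0:
            return 0.0, 1.0, (b, c)
        stat = (b - c) ** 2 / (b + c)
        return float(stat), float(sps.chi2.sf(stat, df=1)), (b, c)
    if method == "exact":
        if b + c == 0:
            return 0.0, 1.0, (b, c)
        p = sps.binomtest(b, b + c, 0.5).pvalue
        return float(min(b, c)), float(p), (b, c)
    raise ValueError("method must be 'chi2' or 'exact'")


def auc_ci_bootstrap(scores, true_labels, n_boot: int = 2000, seed: int = 0,
                     alpha: float = 0.05) -> tuple:
    """Seeded percentile-bootstrap confidence interval for the AUC."""
    s = np.asarray(scores, float).ravel()
    pos = _as_positive_mask(true_labels)
    rng = np.random.default_rng(seed)
    n = s.size
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if pos[idx].all() or not pos[idx].any():
            continue
        aucs.append(roc_curve(s[idx], np.where(pos[idx], 2, 1)).auc)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class ModelReport:
    """One model's row of the evaluation table."""

    auc: float
    optimal_fpr: float
    optimal_tpr: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    mcnemar_statistic: float
    mcnemar_p: float
    discordant: tuple
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "optimal_fpr": self.optimal_fpr,
            "optimal_tpr": self.optimal_tpr,
            "optimal_threshold": self.optimal_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcnemar_statistic": self.mcnemar_statistic,
            "mcnemar_p": self.mcnemar_p,
            "discordant_b": self.discordant[0],
            "discordant_c": self.discordant[1],
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def evaluate_model(scores, true_labels, mcnemar_method: str = "chi2") -> ModelReport:
    """Full evaluation of one score vector: ROC, optimal-point operating
    characteristics, and McNemar of the thresholded labels against truth."""
    roc = roc_curve(scores, true_labels)
    fpr, tpr, thr = roc.optimal
    s = np.asarray(scores, float).ravel()
    pred = np.where(s >= thr, 2, 1)
    truth = np.where(_as_positive_mask(true_labels), 2, 1)
    counts = confusion(truth, pred)
    stat, p, bc = mcnemar(truth, pred, method=mcnemar_method)
    return ModelReport(auc=roc.auc, optimal_fpr=fpr, optimal_tpr=tpr,
                       optimal_threshold=thr,
                       sensitivity=sensitivity(counts),
                       specificity=specificity(counts),
                       mcnemar_statistic=stat, mcnemar_p=p, discordant=bc,
                       counts=counts)
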