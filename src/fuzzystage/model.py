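"""High-level modelling interface for the neuro-fuzzy stage predictor.

:class:`NeuroFuzzyStager` is built from a grouped cohort (or a DataFrame in
the standard column layout) and wires the full pipeline: fuzzy c-means
partitions the training records into the organ-confined and extra-prostatic
clusters, the partition seeds a two-rule Sugeno system, and hybrid adaptive
training tunes its parameters.  ``fit()`` returns a
:class:`NeuroFuzzyStagerResults` carrying the fitted system, the training
trace, the operating threshold and a ``summary()`` table; prediction and
evaluation hang off the results object.

:func:`run_experiment` mirrors the published protocol: one shared 2/3-1/3
split, the neuro-fuzzy model, the standalone FCM classifier and the AJCC
nomogram all evaluated on the same validation subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import anfis as _anfis
from . import evaluation as _eval
from . import fcm as _fcm
from . import fis as _fis
from . import nomogram as _nomo
from .preprocessing import (GroupedPatientRecord, INPUT_NAMES,
                            RawPatientRecord, normalize_cohort)

__all__ = ["NeuroFuzzyStager", "NeuroFuzzyStagerResults", "run_experiment",
           "nomogram_scores_for_records"]


def _frame_to_xy(data: pd.DataFrame):
    missing = [c for c in INPUT_NAMES if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing grouped input columns: {missing}")
    X = data.loc[:, list(INPUT_NAMES)].to_numpy(float)
    y = None
    if "pt_group" in data.columns and data["pt_group"].notna().all():
        y = data["pt_group"].to_numpy(float)
    return X, y


class NeuroFuzzyStager:
    """Neuro-fuzzy predictor of pathological stage (OCD vs ED).

    Parameters
    ----------
    X : (n, 5) array of grouped inputs in the standard order
        (primary Gleason, secondary Gleason, PSA group, age group,
        clinical T group).
    y : length-n targets coded 1 (organ-confined) / 2 (extra-prostatic).
    """

    def __init__(self, X, y, fcm_config: Optional[_fcm.FCMConfig] = None,
                 train_config: Optional[_anfis.TrainConfig] = None):
        self.X = np.atleast_2d(np.asarray(X, float))
        self.y = np.asarray(y, float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y must have the same number of records")
        if not set(np.unique(self.y)) <= {1.0, 2.0}:
            raise ValueError("targets must be coded 1 (OCD) / 2 (ED)")
        self.fcm_config = fcm_config or _fcm.FCMConfig()
        self.train_config = train_config or _anfis.TrainConfig()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "NeuroFuzzyStager":
        X, y = _frame_to_xy(data)
        if y is None:
            raise ValueError("training requires a complete pt_group column")
        return cls(X, y, **kwargs)

    @classmethod
    def from_records(cls, records: Sequence[GroupedPatientRecord],
                     **kwargs) -> "NeuroFuzzyStager":
        X = np.array([r.as_vector() for r in records])
        y = np.array([r.pt_group for r in records], float)
        return cls(X, y, **kwargs)

    def fit(self) -> "NeuroFuzzyStagerResults":
        fcm_result = _fcm.fcm_fit(self.X, self.fcm_config)
        initial = _fis.fis_from_fcm(fcm_result, self.X, self.y)
        trained = _anfis.anfis_train(initial, self.X, self.y, self.train_config)
        scores = _anfis.predict_scores(trained.fis, self.X)
        roc = _eval.roc_curve(scores, self.y)
        return NeuroFuzzyStagerResults(model=self, fcm_result=fcm_result,
                                       initial_fis=initial, fis=trained.fis,
                                       rmse_per_epoch=trained.rmse_per_epoch,
                                       stopped_reason=trained.stopped_reason,
                                       training_roc=roc,
                                       cutoff=roc.optimal[2])


@dataclass
class NeuroFuzzyStagerResults:
    """Fitted neuro-fuzzy stager: parameters, trace and diagnostics.

    The default classification cutoff is the Youden-optimal training-set
    threshold on the raw TSK output (1..2 scale).
    """

    model: NeuroFuzzyStager
    fcm_result: _fcm.FCMResult
    initial_fis: _fis.SugenoFIS
    fis: _fis.SugenoFIS
    rmse_per_epoch: list
    stopped_reason: str
    training_roc: _eval.ROCAnalysis
    cutoff: float

    @property
    def final_rmse(self) -> float:
        return self.rmse_per_epoch[-1] if self.rmse_per_epoch else float("nan")

    def predict(self, X) -> np.ndarray:
        """Raw TSK outputs (ED likelihood on the 1..2 scale) for new records."""
        return _anfis.predict_scores(self.fis, np.atleast_2d(np.asarray(X, float)))

    def predict_labels(self, X, cutoff: Optional[float] = None) -> np.ndarray:
        cut = self.cutoff if cutoff is None else cutoff
        return np.where(self.predict(X) >= cut, 2, 1)

    def evaluate(self, X, y, **kwargs) -> _eval.ModelReport:
        """Full ROC/McNemar report on a held-out subset."""
        return _eval.evaluate_model(self.predict(X), y, **kwargs)

    def summary(self) -> str:
        """A statsmodels-style text summary of the fitted system."""
        lines = ["Neuro-Fuzzy Pathological Stage Predictor",
                 "=" * 56,
                 f"records:            {self.model.X.shape[0]}",
                 f"inputs:             {', '.join(INPUT_NAMES)}",
                 f"rules:              {len(self.fis.rules)}",
                 f"training epochs:    {len(self.rmse_per_epoch)} "
                 f"(stopped: {self.stopped_reason})",
                 f"final train RMSE:   {self.final_rmse:.6f}",
                 f"train AUC:          {self.training_roc.auc:.4f}",
                 f"operating cutoff:   {self.cutoff:.4f}  (Youden-optimal)",
                 "-" * 56]
        for i, rule in enumerate(self.fis.rules, 1):
            lines.append(f"Rule {i} [{rule.class_tag}]")
            for name, mf in zip(self.fis.input_names, rule.antecedent):
                lines.append(f"  {name:<18s} center={mf.center:8.4f} "
                             f"width={mf.width:7.4f}")
            coef = ", ".join(f"{a:.4f}" for a in rule.consequent)
            lines.append(f"  consequent         [{coef}]")
        return "\n".join(lines)


def nomogram_scores_for_records(raw_records: Sequence[RawPatientRecord]) -> np.ndarray:
    """AJCC 2010 stage-group scores (1-5) for raw records.

    The cohort has no clinical N/M columns, so N0/M0 are assumed; the
    Gleason score is the sum of the two biopsy patterns.
    """
    scores = np.empty(len(raw_records))
    for i, r in enumerate(raw_records):
        tnm = _nomo.TNMInput(t_code=r.clinical_t, n_code="N0", m_code="M0",
                             psa=r.psa_ng_ml,
                             gleason_sum=r.primary_gleason + r.secondary_gleason)
        scores[i] = _nomo.nomogram_score(tnm)
    return scores


def run_experiment(raw_records: Sequence[RawPatientRecord],
                   seed: int = 0,
                   train_fraction: float = 2.0 / 3.0,
                   stratified: bool = False,
                   fcm_config: Optional[_fcm.FCMConfig] = None,
                   train_config: Optional[_anfis.TrainConfig] = None,
                   include_comparators: bool = False,
                   mcnemar_method: str = "chi2") -> dict:
    """The published protocol on one cohort: shared split, three models.

    Normalises the cohort, splits once, fits the neuro-fuzzy model on the
    training subset and evaluates it, the standalone FCM classifier and
    the AJCC nomogram baseline on the same validation subset.  With
    ``include_comparators=True`` adds non-normative scikit-learn ANN/SVM/
    naive-Bayes rows.  Returns a dict with per-model
    :class:`~fuzzystage.evaluation.ModelReport` entries and the fitted
    results object.
    """
    raw_records = list(raw_records)
    grouped = normalize_cohort(raw_records)
    if any(g.pt_group is None for g in grouped):
        raise ValueError("the experiment requires pathological outcomes")
    idx_train, idx_val = _eval.split_cohort(
        list(range(len(grouped))), train_fraction=train_fraction, seed=seed,
        stratified=stratified,
        labels=[g.pt_group for g in grouped] if stratified else None)

    X = np.array([g.as_vector() for g in grouped])
    y = np.array([g.pt_group for g in grouped], float)
    Xtr, ytr = X[idx_train], y[idx_train]
    Xva, yva = X[idx_val], y[idx_val]

    fcm_config = fcm_config or _fcm.FCMConfig(seed=seed)
    train_config = train_config or _anfis.TrainConfig(seed=seed)
    model = NeuroFuzzyStager(Xtr, ytr, fcm_config=fcm_config,
                             train_config=train_config)
    results = model.fit()

    reports = {}
    reports["neuro_fuzzy"] = results.evaluate(Xva, yva,
                                              mcnemar_method=mcnemar_method)
    reports["initial_fis"] = _eval.evaluate_model(
        _anfis.predict_scores(results.initial_fis, Xva), yva,
        mcnemar_method=mcnemar_method)

    # standalone FCM classifier: membership in the ED-assigned cluster
    cmap, _, _ = _fcm.fcm_classify(results.fcm_result, ytr)
    u_val = np.array([_fcm.fcm_membership(x, results.fcm_result.centers,
                                          fcm_config.m) for x in Xva])
    reports["fcm"] = _eval.evaluate_model(u_val[:, cmap.ed_cluster], yva,
                                          mcnemar_method=mcnemar_method)

    nomo_scores = nomogram_scores_for_records(
        [raw_records[i] for i in idx_val])
    reports["nomogram"] = _eval.evaluate_model(nomo_scores, yva,
                                               mcnemar_method=mcnemar_method)

    if include_comparators:
        reports.update(_comparator_reports(Xtr, ytr, Xva, yva,
                                           seed=seed,
                                           mcnemar_method=mcnemar_method))

    return {"reports": reports, "results": results,
            "split": {"train": idx_train, "validation": idx_val},
            "n": len(grouped)}


def _comparator_reports(Xtr, ytr, Xva, yva, seed=0, mcnemar_method="chi2"):
    """Non-normative library comparators (neural net, SVM, naive Bayes)."""
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    out = {}
    models = {
        "ann_mlp": MLPClassifier(hidden_layer_sizes=(5,), max_iter=2000,
                                 random_state=seed),
        "svm_quadratic": SVC(kernel="poly", degree=2, probability=True,
                             random_state=seed),
        "naive_bayes_gaussian": GaussianNB(),
    }
    for name, est in models.items():
        est.fit(Xtr, ytr)
        proba = est.predict_proba(Xva)[:, list(est.classes_).index(2.0)]
        out[name] = _eval.evaluate_model(proba, yva,
                                         mcnemar_method=mcnemar_method)
    return out


def reports_to_frame(reports: dict) -> pd.DataFrame:
    """Stack per-model reports into the published comparison-table layout."""
    rows = {name: rep.to_dict() for name, rep in reports.items()}
    return pd.DataFrame(rows).T[["auc", "optimal_fpr", "optimal_tpr",
                                 "mcnemar_p", "sensitivity", "specificity"]]
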