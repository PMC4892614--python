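"""Adaptive training of the Sugeno system against known outcomes.

Hybrid learning in the classic Type-3 style: each epoch solves the rule
consequents by global least squares given the current premises, then moves
every membership-function center and width one normalised-gradient-descent
step on the squared prediction error.  The step length adapts (x1.1 after
four consecutive error decreases) and an epoch whose premise update raises
the training RMSE is rolled back with the step shrunk (x0.9), so the
recorded RMSE trace is non-increasing and the stopping rule — epoch cap or
error goal — is well behaved.

Targets are coded 1 = organ-confined disease, 2 = extra-prostatic disease;
the raw TSK output is therefore an ED-likelihood on the 1..2 scale, with a
companion normalised score s = clamp(y_hat - 1, 0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fis import (SugenoFIS, _firing_matrix, _parameter_arrays, infer,
                  infer_batch, solve_consequents)
from .preprocessing import GroupedPatientRecord

__all__ = ["TrainConfig", "TrainResult", "rmse", "anfis_train",
           "predict_score", "classify"]

WIDTH_CLAMP = 0.01  # premise widths never shrink below this during training


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    error_goal: float = 0.0
    method: str = "hybrid"        # "hybrid" or "gradient"
    consequent_order: int = 1     # 1 = linear TSK, 0 = constant consequents
    initial_step: float = 0.01
    step_increase: float = 1.1    # after 4 consecutive error decreases
    step_decrease: float = 0.9    # after a rejected (oscillating) epoch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")
        if self.method not in ("hybrid", "gradient"):
            raise ValueError("method must be 'hybrid' or 'gradient'")


@dataclass
class TrainResult:
    fis: SugenoFIS
    rmse_per_epoch: list[float]
    stopped_reason: str           # "epochs" or "error_goal"


def rmse(predictions: Sequence[float], targets: Sequence[float]) -> float:
    """Root mean square error between two equal-length sequences."""
    p = np.asarray(predictions, float).ravel()
    t = np.asarray(targets, float).ravel()
    if p.size == 0 or p.size != t.size:
        raise ValueError("predictions and targets must be equal-length and non-empty")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def _premise_gradient(fis: SugenoFIS, X: np.ndarray, y: np.ndarray):
    """Gradient of sum of squared errors wrt all MF centers and widths."""
    centers, widths, conseq = _parameter_arrays(fis)
    w = _firing_matrix(X, centers, widths)                    # (n, r)
    f = X @ conseq[:, 1:].T + conseq[:, 0]                    # (n, r)
    total = w.sum(axis=1)
    safe = np.where(total > 0.0, total, 1.0)
    yhat = np.sum(w * f, axis=1) / safe
    e = yhat - y                                              # (n,)
    # d y_hat / d w_i = (f_i - y_hat) / W
    common = (2.0 * e / safe)[:, None] * (f - yhat[:, None]) * w   # (n, r)
    diff = X[:, None, :] - centers[None, :, :]                # (n, r, d)
    grad_c = np.einsum("nr,nrd->rd", common, diff / widths[None] ** 2)
    grad_w = np.einsum("nr,nrd->rd", common, diff ** 2 / widths[None] ** 3)
    return grad_c, grad_w, float(np.sqrt(np.mean(e ** 2)))


def _get_premises(fis: SugenoFIS):
    return ([[ (mf.center, mf.width) for mf in r.antecedent] for r in fis.rules],
            [r.consequent.copy() for r in fis.rules])


def _set_premises(fis: SugenoFIS, snapshot) -> None:
    prem, cons = snapshot
    for rule, mfs, coef in zip(fis.rules, prem, cons):
        for mf, (c, w) in zip(rule.antecedent, mfs):
            mf.center, mf.width = c, w
        rule.consequent = coef.copy()


def anfis_train(fis: SugenoFIS, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig = TrainConfig()) -> TrainResult:
    """Tune the FIS parameters against 1/2-coded outcomes.

    Returns a :class:`TrainResult` whose FIS is the best (lowest training
    RMSE) state visited.  With ``epochs=0`` the input system is returned
    unchanged with an empty RMSE trace.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[1] != fis.n_inputs:
        raise ValueError("X width must match the FIS input dimension")
    if X.shape[0] != y.size:
        raise ValueError("X and y must have the same number of records")
    work = fis.copy()
    if cfg.epochs == 0:
        return TrainResult(fis=work, rmse_per_epoch=[], stopped_reason="epochs")
    n_coef = len(work.rules) * (work.n_inputs + 1 if cfg.consequent_order == 1 else 1)
    if cfg.method == "hybrid" and X.shape[0] < n_coef:
        raise ValueError(f"hybrid training needs at least {n_coef} records "
                         f"for the consequent least-squares solve, got {X.shape[0]}")

    step = cfg.initial_step
    streak = 0
    best_rmse = np.inf
    best = _get_premises(work)
    trace: list[float] = []
    reason = "epochs"
    for _epoch in range(cfg.epochs):
        if cfg.method == "hybrid":
            solve_consequents(work, X, y, order=cfg.consequent_order)
        grad_c, grad_w, r = _premise_gradient(work, X, y)
        if not (np.all(np.isfinite(grad_c)) and np.all(np.isfinite(grad_w))):
            raise FloatingPointError("non-finite premise gradient encountered "
                                     "during ANFIS training")
        if r <= best_rmse:
            best_rmse = r
            best = _get_premises(work)
            streak += 1
            if streak >= 4:
                step *= cfg.step_increase
                streak = 0
        else:
            _set_premises(work, best)   # reject the oscillating premise update
            step *= cfg.step_decrease
            streak = 0
            grad_c, grad_w, r = _premise_gradient(work, X, y)
        trace.append(best_rmse)
        if best_rmse <= cfg.error_goal:
            reason = "error_goal"
            break
        norm = float(np.sqrt(np.sum(grad_c ** 2) + np.sum(grad_w ** 2)))
        if norm > 0.0:
            centers, widths, _ = _parameter_arrays(work)
            centers = centers - step * grad_c / norm
            widths = np.maximum(widths - step * grad_w / norm, WIDTH_CLAMP)
            for rule, crow, wrow in zip(work.rules, centers, widths):
                for mf, c, w in zip(rule.antecedent, crow, wrow):
                    mf.center, mf.width = float(c), float(w)
    _set_premises(work, best)
    return TrainResult(fis=work, rmse_per_epoch=trace, stopped_reason=reason)


def predict_score(fis: SugenoFIS, record) -> tuple[float, float]:
    """ED-likelihood of one record: raw TSK output and normalised score.

    Accepts a :class:`GroupedPatientRecord` or a plain input vector.
    Returns ``(y_hat, s)`` with ``s = clamp(y_hat - 1, 0, 1)``.
    """
    if isinstance(record, GroupedPatientRecord):
        x = record.as_vector()
    else:
        x = np.asarray(record, float).ravel()
    if x.shape[0] != fis.n_inputs or not np.all(np.isfinite(x)):
        raise ValueError("record does not match the FIS inputs")
    yhat, _ = infer(fis, x)
    return yhat, float(np.clip(yhat - 1.0, 0.0, 1.0))


def predict_scores(fis: SugenoFIS, X: np.ndarray) -> np.ndarray:
    """Vectorised raw TSK outputs for the rows of X."""
    return infer_batch(fis, X)


def classify(score: float, cutoff: float) -> str:
    """Threshold an ED score: 'ED' iff score >= cutoff, else 'OCD'."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return "ED" if score >= cutoff else "OCD"
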