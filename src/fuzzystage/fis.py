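"""Sugeno-type fuzzy inference system (the ANFIS forward pass).

One Takagi-Sugeno-Kang rule per disease cluster.  Each rule's antecedent
is one Gaussian membership function per input; firing strengths use the
product t-norm; the output is the firing-strength-weighted average of the
rules' (by default first-order linear) consequents — layers 1-5 of the
adaptive neuro-fuzzy architecture.

The initial system is constructed from a fuzzy c-means result: membership
function centers come from the cluster centers, widths from the
membership-weighted spread of the data, and consequents from one global
least-squares solve of the normalised-firing linear system.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fcm import FCMResult, fcm_classify
from .preprocessing import GROUP_RANGES, INPUT_NAMES

__all__ = ["GaussianMF", "Rule", "SugenoFIS", "mf_eval", "rule_firing",
           "infer", "fis_from_fcm"]

WIDTH_FLOOR = 0.1  # minimal MF width at construction (ordinal inputs)


@dataclass
class GaussianMF:
    """Gaussian membership function exp(-(x-c)^2 / (2 w^2))."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("membership function width must be positive")


@dataclass
class Rule:
    """A TSK rule: Gaussian antecedents plus a linear consequent.

    The consequent is f(x) = a0 + a1 x1 + ... + ad xd (first order); a
    zeroth-order rule has only a0 with the rest zero.
    """

    antecedent: list            # one GaussianMF per input
    consequent: np.ndarray      # length d+1, [a0, a1..ad]
    class_tag: str = ""         # "OCD" or "ED"

    def evaluate_consequent(self, x: np.ndarray) -> float:
        return float(self.consequent[0] + np.dot(self.consequent[1:], x))


@dataclass
class SugenoFIS:
    input_names: tuple = INPUT_NAMES
    input_ranges: dict = field(default_factory=lambda: dict(GROUP_RANGES))
    rules: list = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    def __post_init__(self) -> None:
        for r in self.rules:
            if len(r.antecedent) != self.n_inputs:
                raise ValueError("rule antecedent length must equal input count")

    # -- serialization (bit-exact interchange for train/predict) ----------

    def to_dict(self) -> dict:
        return {
            "input_names": list(self.input_names),
            "input_ranges": {k: list(v) for k, v in self.input_ranges.items()},
            "rules": [{
                "class_tag": r.class_tag,
                "antecedent": [{"center": mf.center, "width": mf.width}
                               for mf in r.antecedent],
                "consequent": [float(a) for a in r.consequent],
            } for r in self.rules],
        }

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc + "\n")
        return doc

    @classmethod
    def from_dict(cls, d: dict) -> "SugenoFIS":
        rules = [Rule(antecedent=[GaussianMF(mf["center"], mf["width"])
                                  for mf in r["antecedent"]],
                      consequent=np.asarray(r["consequent"], float),
                      class_tag=r.get("class_tag", ""))
                 for r in d["rules"]]
        return cls(input_names=tuple(d["input_names"]),
                   input_ranges={k: tuple(v) for k, v in d["input_ranges"].items()},
                   rules=rules)

    @classmethod
    def from_json(cls, source) -> "SugenoFIS":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        try:
            return cls.from_dict(json.loads(source))
        except (ValueError, TypeError):
            with open(source, encoding="utf-8") as fh:
                return cls.from_dict(json.load(fh))

    def copy(self) -> "SugenoFIS":
        return SugenoFIS.from_dict(self.to_dict())


def mf_eval(mf: GaussianMF, x: float) -> float:
    """Membership grade exp(-(x - c)^2 / (2 w^2)) in [0, 1]."""
    z = (float(x) - mf.center) / mf.width
    return float(np.exp(-0.5 * z * z))


def rule_firing(rule: Rule, x: Sequence[float]) -> float:
    """Product t-norm over the rule's per-input membership grades."""
    x = np.asarray(x, float).ravel()
    if x.shape[0] != len(rule.antecedent):
        raise ValueError("input dimension does not match rule antecedent")
    w = 1.0
    for mf, xi in zip(rule.antecedent, x):
        w *= mf_eval(mf, xi)
    return w


def infer(fis: SugenoFIS, x: Sequence[float]):
    """TSK inference: firing-strength-weighted average of rule consequents.

    Returns ``(output, detail)`` where detail carries the per-rule firing
    strengths ``w``, their normalised values ``w_bar`` and the consequent
    values ``f``.  If every firing strength underflows to zero, the nearest
    rule's consequent (by antecedent-center distance) is returned with a
    warning.
    """
    x = np.asarray(x, float).ravel()
    if x.shape[0] != fis.n_inputs:
        raise ValueError(f"expected {fis.n_inputs} inputs, got {x.shape[0]}")
    w = np.array([rule_firing(r, x) for r in fis.rules])
    f = np.array([r.evaluate_consequent(x) for r in fis.rules])
    total = w.sum()
    if total <= 0.0:
        warnings.warn("all rule firing strengths underflowed to zero; "
                      "falling back to the nearest rule's consequent",
                      stacklevel=2)
        centers = np.array([[mf.center for mf in r.antecedent] for r in fis.rules])
        nearest = int(np.argmin(np.sum((centers - x) ** 2, axis=1)))
        w_bar = np.zeros_like(w)
        w_bar[nearest] = 1.0
        return float(f[nearest]), {"w": w, "w_bar": w_bar, "f": f}
    w_bar = w / total
    return float(np.dot(w_bar, f)), {"w": w, "w_bar": w_bar, "f": f}


def infer_batch(fis: SugenoFIS, X: np.ndarray) -> np.ndarray:
    """Vectorised inference over the rows of X (n, d)."""
    X = np.atleast_2d(np.asarray(X, float))
    centers, widths, conseq = _parameter_arrays(fis)
    w = _firing_matrix(X, centers, widths)                    # (n, r)
    f = X @ conseq[:, 1:].T + conseq[:, 0]                    # (n, r)
    total = w.sum(axis=1)
    out = np.empty(X.shape[0])
    ok = total > 0.0
    out[ok] = np.sum(w[ok] * f[ok], axis=1) / total[ok]
    if not ok.all():
        warnings.warn("zero total firing strength for some records; using "
                      "nearest-rule consequents", stacklevel=2)
        for i in np.flatnonzero(~ok):
            nearest = int(np.argmin(np.sum((centers - X[i]) ** 2, axis=1)))
            out[i] = f[i, nearest]
    return out


def _parameter_arrays(fis: SugenoFIS):
    centers = np.array([[mf.center for mf in r.antecedent] for r in fis.rules])
    widths = np.array([[mf.width for mf in r.antecedent] for r in fis.rules])
    conseq = np.array([r.consequent for r in fis.rules])
    return centers, widths, conseq


def _firing_matrix(X: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    z = (X[:, None, :] - centers[None, :, :]) / widths[None, :, :]
    return np.exp(-0.5 * np.sum(z * z, axis=2))


def fis_from_fcm(fcm_result: FCMResult, data: np.ndarray, targets: np.ndarray,
                 input_names: tuple = INPUT_NAMES,
                 input_ranges: Optional[dict] = None,
                 order: int = 1) -> SugenoFIS:
    """Build the initial Sugeno system from a fuzzy c-means partition.

    One rule per cluster.  Antecedent centers are the cluster-center
    coordinates; widths are the membership-weighted standard deviation of
    the data around the center in each dimension (floored at 0.1).
    Consequents come from a single global least-squares solve of the
    normalised-firing linear system against the 1/2 targets (ridge
    fallback, lambda=1e-6, if the system is singular); ``order=0`` fits
    per-rule constants instead.
    """
    data = np.atleast_2d(np.asarray(data, float))
    targets = np.asarray(targets, float).ravel()
    centers = fcm_result.centers
    u = fcm_result.membership
    c, d = centers.shape
    if input_ranges is None:
        input_ranges = dict(GROUP_RANGES) if tuple(input_names) == INPUT_NAMES else {
            n: (float(data[:, j].min()), float(data[:, j].max()))
            for j, n in enumerate(input_names)}

    um = u ** (fcm_result.config.m if fcm_result.config else 2.0)
    widths = np.empty_like(centers)
    for k in range(c):
        var = (um[:, k][:, None] * (data - centers[k]) ** 2).sum(axis=0) / um[:, k].sum()
        widths[k] = np.maximum(np.sqrt(var), WIDTH_FLOOR)

    # class tags from the majority-vote cluster map
    cmap, _, _ = fcm_classify(fcm_result, targets)
    tags = ["ED" if cls == 2 else "OCD" for cls in cmap.cluster_class]

    rules = [Rule(antecedent=[GaussianMF(float(centers[k, j]), float(widths[k, j]))
                              for j in range(d)],
                  consequent=np.zeros(d + 1), class_tag=tags[k])
             for k in range(c)]
    fis = SugenoFIS(input_names=tuple(input_names), input_ranges=input_ranges,
                    rules=rules)
    solve_consequents(fis, data, targets, order=order)
    return fis


def solve_consequents(fis: SugenoFIS, X: np.ndarray, y: np.ndarray,
                      order: int = 1) -> None:
    """Least-squares consequent fit given the current premises (in place).

    Builds the layer-4 design matrix with rows ``concat_k( w_bar_k * [1, x] )``
    (or ``w_bar_k`` alone for order 0) and solves for all rules jointly.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    centers, widths, _ = _parameter_arrays(fis)
    w = _firing_matrix(X, centers, widths)
    total = w.sum(axis=1, keepdims=True)
    total[total <= 0.0] = 1.0
    wbar = w / total                                        # (n, r)
    n, d = X.shape
    r = len(fis.rules)
    if order == 1:
        basis = np.hstack([np.ones((n, 1)), X])             # (n, d+1)
        A = (wbar[:, :, None] * basis[:, None, :]).reshape(n, r * (d + 1))
        ncoef = d + 1
    elif order == 0:
        A = wbar
        ncoef = 1
    else:
        raise ValueError("order must be 0 or 1")

    coefs, *_ = np.linalg.lstsq(A, y, rcond=None)
    if not np.all(np.isfinite(coefs)):
        warnings.warn("singular consequent system; using ridge fallback "
                      "(lambda=1e-6)", stacklevel=2)
        lam = 1e-6
        coefs = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]), A.T @ y)
    for k, rule in enumerate(fis.rules):
        full = np.zeros(d + 1)
        if order == 1:
            full[:] = coefs[k * ncoef:(k + 1) * ncoef]
        else:
            full[0] = coefs[k]
        rule.consequent = full
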