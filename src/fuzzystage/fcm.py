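"""Fuzzy C-Means clustering.

Soft clustering by alternating minimisation of the membership-weighted
within-cluster sum of squares

    J(U, V) = sum_i sum_k u_ik^m ||x_k - v_i||^2,   m > 1,

where U is the (row-stochastic over clusters) membership matrix and V the
cluster centers.  Here it both seeds the Sugeno fuzzy inference system and
serves as a standalone two-class (organ-confined vs extra-prostatic)
classifier via a majority-vote cluster-to-class map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["FCMConfig", "FCMResult", "fcm_objective", "fcm_membership",
           "fcm_fit", "fcm_classify", "ClusterClassMap"]


@dataclass(frozen=True)
class FCMConfig:
    c: int = 2                 # number of clusters
    m: float = 2.0             # fuzzifier exponent, > 1
    tol: float = 1e-5          # stop when max |delta U| < tol
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("cluster count c must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FCMResult:
    centers: np.ndarray                # (c, n_features)
    membership: np.ndarray             # (n, c), rows sum to 1
    objective_trajectory: list[float]
    iterations: int
    config: Optional[FCMConfig] = None

    def to_json(self) -> str:
        return json.dumps({
            "centers": self.centers.tolist(),
            "membership": self.membership.tolist(),
            "objective_trajectory": list(map(float, self.objective_trajectory)),
            "iterations": self.iterations,
        })


def fcm_objective(data: np.ndarray, centers: np.ndarray,
                  membership: np.ndarray, m: float) -> float:
    """The FCM objective J = sum_ik u_ik^m ||x_k - v_i||^2 (Euclidean)."""
    data = np.atleast_2d(np.asarray(data, float))
    centers = np.atleast_2d(np.asarray(centers, float))
    membership = np.atleast_2d(np.asarray(membership, float))
    n, c = membership.shape
    if data.shape[0] != n or centers.shape[0] != c or data.shape[1] != centers.shape[1]:
        raise ValueError("inconsistent shapes for data/centers/membership")
    d2 = _sq_distances(data, centers)          # (n, c)
    return float(np.sum(membership ** m * d2))


def fcm_membership(point: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership of one point in each cluster (the FCM update formula).

    u_i = 1 / sum_j (d_i / d_j)^(2/(m-1)); a point coinciding with a center
    gets full membership in that center.
    """
    point = np.asarray(point, float).ravel()
    centers = np.atleast_2d(np.asarray(centers, float))
    d2 = np.sum((centers - point) ** 2, axis=1)
    return _membership_from_d2(d2[None, :], m)[0]


def _sq_distances(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = data[:, None, :] - centers[None, :, :]
    return np.sum(diff * diff, axis=2)


def _membership_from_d2(d2: np.ndarray, m: float) -> np.ndarray:
    """Row-wise membership update from squared distances (n, c)."""
    n, c = d2.shape
    u = np.empty_like(d2)
    zero = d2 <= 0.0
    rows_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        p = d2 ** (-1.0 / (m - 1.0))          # d^{-2/(m-1)}
    u[~rows_zero] = p[~rows_zero] / p[~rows_zero].sum(axis=1, keepdims=True)
    # zero-distance convention: all mass on the coincident center(s)
    if rows_zero.any():
        z = zero[rows_zero].astype(float)
        u[rows_zero] = z / z.sum(axis=1, keepdims=True)
    return u


def fcm_fit(data: np.ndarray, config: FCMConfig = FCMConfig()) -> FCMResult:
    """Run FCM from a seeded random row-normalised membership matrix.

    Alternates the center update v_i = sum_k u_ik^m x_k / sum_k u_ik^m and
    the membership update until max |delta U| < tol or max_iter.
    """
    data = np.atleast_2d(np.asarray(data, float))
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    n = data.shape[0]
    if n < config.c:
        raise ValueError(f"need at least c={config.c} points, got {n}")
    rng = np.random.default_rng(config.seed)
    u = rng.uniform(size=(n, config.c))
    u /= u.sum(axis=1, keepdims=True)

    m = config.m
    trajectory: list[float] = []
    it = 0
    for it in range(1, config.max_iter + 1):
        um = u ** m
        centers = (um.T @ data) / um.sum(axis=0)[:, None]
        d2 = _sq_distances(data, centers)
        u_new = _membership_from_d2(d2, m)
        trajectory.append(float(np.sum(u_new ** m * d2)))
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        if delta < config.tol:
            break

    if np.any(_sq_distances(centers, centers) + np.eye(config.c) <= 1e-12):
        warnings.warn("FCM converged with coincident cluster centers "
                      "(degenerate data?)", stacklevel=2)
    return FCMResult(centers=centers, membership=u,
                     objective_trajectory=trajectory, iterations=it,
                     config=config)


@dataclass(frozen=True)
class ClusterClassMap:
    """Majority-vote assignment of clusters to outcome classes (1=OCD, 2=ED)."""

    cluster_class: tuple        # class label per cluster index
    ed_cluster: int             # index of the cluster mapped to ED (class 2)


def fcm_classify(result: FCMResult, labels: np.ndarray):
    """Map clusters to classes by majority vote and score records toward ED.

    Each cluster takes the majority class of its maximum-membership members
    (ties broken toward ED, the disease-positive class).  If every cluster
    lands on the same class, the most (respectively least) ED-heavy cluster
    is forced to ED (respectively OCD) so that both classes are always
    represented.  A record's ED score is its membership in the ED-assigned
    cluster.  Returns ``(ClusterClassMap, hard_labels, ed_scores)``.
    """
    labels = np.asarray(labels)
    u = result.membership
    if labels.shape[0] != u.shape[0]:
        raise ValueError("labels must match the fitted data")
    hard = np.argmax(u, axis=1)
    c = u.shape[1]
    cluster_class = []
    for k in range(c):
        members = labels[hard == k]
        if members.size == 0:
            raise ValueError(f"cluster {k} has no maximum-membership members")
        n_ed = int(np.sum(members == 2))
        cluster_class.append(2 if n_ed * 2 >= members.size else 1)
    frac = [float(np.mean(labels[hard == k] == 2)) for k in range(c)]
    if 2 not in cluster_class:
        # force the most ED-heavy cluster to represent ED so a score exists
        cluster_class[int(np.argmax(frac))] = 2
    if 1 not in cluster_class and c >= 2:
        # symmetric fix: the least ED-heavy cluster represents OCD
        cluster_class[int(np.argmin(frac))] = 1
    ed_cluster = int(cluster_class.index(2))
    cmap = ClusterClassMap(cluster_class=tuple(cluster_class), ed_cluster=ed_cluster)
    hard_labels = np.array([cluster_class[k] for k in hard])
    ed_scores = u[:, ed_cluster].copy()
    return cmap, hard_labels, ed_scores
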