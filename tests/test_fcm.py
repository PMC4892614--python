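"""Fuzzy c-means: closed forms, invariants and a brute-force oracle."""

import numpy as np
import pytest

from fuzzystage.fcm import (FCMConfig, fcm_classify, fcm_fit, fcm_membership,
                            fcm_objective)


# ---------------------------------------------------------------- oracle

def oracle_membership(data, centers, m):
    """Direct per-point evaluation of the membership update formula."""
    n, c = data.shape[0], centers.shape[0]
    u = np.zeros((n, c))
    for k in range(n):
        d = [np.linalg.norm(data[k] - centers[i]) for i in range(c)]
        if min(d) == 0.0:
            hits = [i for i in range(c) if d[i] == 0.0]
            for i in hits:
                u[k, i] = 1.0 / len(hits)
            continue
        for i in range(c):
            u[k, i] = 1.0 / sum((d[i] / d[j]) ** (2.0 / (m - 1.0))
                                for j in range(c))
    return u


def oracle_fixed_point(data, c, m, u0, n_iter=500):
    """Independent alternating fixed-point iteration run to stagnation."""
    u = u0.copy()
    for _ in range(n_iter):
        centers = np.zeros((c, data.shape[1]))
        for i in range(c):
            w = u[:, i] ** m
            centers[i] = (w[:, None] * data).sum(axis=0) / w.sum()
        u_new = oracle_membership(data, centers, m)
        if np.max(np.abs(u_new - u)) < 1e-14:
            u = u_new
            break
        u = u_new
    return centers, u


def oracle_objective(data, centers, u, m):
    total = 0.0
    for k in range(data.shape[0]):
        for i in range(centers.shape[0]):
            total += u[k, i] ** m * np.linalg.norm(data[k] - centers[i]) ** 2
    return total


# ------------------------------------------------------------- objective

def test_objective_zero_for_coincident_points():
    data = np.array([[1.0, 2.0], [3.0, 4.0]])
    u = np.eye(2)
    assert fcm_objective(data, data, u, m=2.0) == 0.0


def test_objective_single_point_closed_form():
    d = 3.0
    assert fcm_objective([[d, 0.0]], [[0.0, 0.0]], [[1.0]], m=2.0) == pytest.approx(d ** 2)


def test_objective_matches_double_sum_oracle():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(5, 3))
    centers = rng.normal(size=(2, 3))
    u = rng.uniform(size=(5, 2))
    u /= u.sum(axis=1, keepdims=True)
    assert fcm_objective(data, centers, u, m=2.0) == pytest.approx(
        oracle_objective(data, centers, u, 2.0), abs=1e-12)


def test_objective_shape_mismatch():
    with pytest.raises(ValueError):
        fcm_objective(np.zeros((3, 2)), np.zeros((2, 2)), np.zeros((4, 2)), 2.0)


# ------------------------------------------------------------ membership

def test_membership_equidistant_point_is_symmetric():
    u = fcm_membership([0.0, 0.0], [[-1.0, 0.0], [1.0, 0.0]], m=2.0)
    assert u == pytest.approx([0.5, 0.5])


def test_membership_at_center_is_one_hot():
    u = fcm_membership([1.0, 1.0], [[1.0, 1.0], [5.0, 5.0]], m=2.0)
    assert u == pytest.approx([1.0, 0.0])


def test_membership_distance_ratio_example():
    # distances (1, 2) with m = 2 give (0.8, 0.2)
    u = fcm_membership([0.0], [[1.0], [-2.0]], m=2.0)
    assert u == pytest.approx([0.8, 0.2])


# --------------------------------------------------------------- fitting

def test_fit_separable_clouds_memberships_crisp():
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 0.05, size=(20, 2))
    b = rng.normal(0.0, 0.05, size=(20, 2)) + 50.0
    data = np.vstack([a, b])
    res = fcm_fit(data, FCMConfig(seed=2))
    own = np.max(res.membership, axis=1)
    assert np.all(own >= 0.99)


def test_fit_agrees_with_fixed_point_oracle():
    data = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
    cfg = FCMConfig(c=2, m=2.0, tol=1e-12, max_iter=1000, seed=3)
    res = fcm_fit(data, cfg)
    # the oracle starts from the same seeded initial membership matrix
    rng = np.random.default_rng(cfg.seed)
    u0 = rng.uniform(size=(6, 2))
    u0 /= u0.sum(axis=1, keepdims=True)
    centers, u = oracle_fixed_point(data, 2, 2.0, u0)
    assert res.centers == pytest.approx(centers, abs=1e-3)
    assert res.membership == pytest.approx(u, abs=1e-6)


def test_fit_invariants_membership_rows_and_objective_monotone(default_grouped):
    X = np.array([r.as_vector() for r in default_grouped[:150]])
    res = fcm_fit(X, FCMConfig(seed=0))
    assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((res.membership >= 0) & (res.membership <= 1))
    traj = np.array(res.objective_trajectory)
    assert np.all(np.diff(traj) <= 1e-10)


def test_fit_deterministic_given_seed():
    rng = np.random.default_rng(9)
    data = rng.normal(size=(30, 4))
    r1 = fcm_fit(data, FCMConfig(seed=42))
    r2 = fcm_fit(data, FCMConfig(seed=42))
    assert np.array_equal(r1.centers, r2.centers)
    assert np.array_equal(r1.membership, r2.membership)


def test_fit_too_few_points_and_degenerate_data():
    with pytest.raises(ValueError):
        fcm_fit(np.zeros((1, 2)), FCMConfig(c=2))
    with pytest.warns(UserWarning):
        fcm_fit(np.ones((5, 2)), FCMConfig(seed=0))


def test_oracle_equivalence_on_random_small_instances():
    rng = np.random.default_rng(7)
    for _ in range(5):
        data = rng.normal(size=(8, 2)) * rng.uniform(0.5, 3.0)
        cfg = FCMConfig(c=2, tol=1e-13, max_iter=2000, seed=int(rng.integers(100)))
        res = fcm_fit(data, cfg)
        u_oracle = oracle_membership(data, res.centers, cfg.m)
        assert res.membership == pytest.approx(u_oracle, abs=1e-6)


# ---------------------------------------------------------- classification

def test_classify_separated_clusters_perfect_training_accuracy():
    rng = np.random.default_rng(11)
    a = rng.normal(0, 0.1, size=(15, 2))
    b = rng.normal(8, 0.1, size=(15, 2))
    data = np.vstack([a, b])
    labels = np.array([1] * 15 + [2] * 15)
    res = fcm_fit(data, FCMConfig(seed=0))
    _, hard, scores = fcm_classify(res, labels)
    assert np.array_equal(hard, labels)
    # ED scores separate the classes perfectly
    assert scores[labels == 2].min() > scores[labels == 1].max()


def test_classify_label_swap_swaps_cluster_map():
    rng = np.random.default_rng(11)
    data = np.vstack([rng.normal(0, 0.1, size=(15, 2)),
                      rng.normal(8, 0.1, size=(15, 2))])
    labels = np.array([1] * 15 + [2] * 15)
    res = fcm_fit(data, FCMConfig(seed=0))
    cmap_a, _, _ = fcm_classify(res, labels)
    cmap_b, _, _ = fcm_classify(res, 3 - labels)
    assert cmap_a.cluster_class == tuple(3 - c for c in cmap_b.cluster_class)


def test_classify_default_cohort_both_classes_represented(default_grouped):
    """On the default cohort both classes get a cluster, every record gets a
    hard label, and the ED-tagged cluster is at least as ED-enriched as the
    OCD-tagged one."""
    X = np.array([r.as_vector() for r in default_grouped])
    y = np.array([r.pt_group for r in default_grouped])
    res = fcm_fit(X, FCMConfig(seed=1))
    cmap, hard, scores = fcm_classify(res, y)
    assert set(cmap.cluster_class) == {1, 2}
    assert set(hard) <= {1, 2}
    argmax = np.argmax(res.membership, axis=1)
    frac_ed_cluster = np.mean(y[argmax == cmap.ed_cluster] == 2)
    frac_ocd_cluster = np.mean(y[argmax != cmap.ed_cluster] == 2)
    assert frac_ed_cluster >= frac_ocd_cluster
    assert scores.shape == y.shape and np.all((0 <= scores) & (scores <= 1))
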