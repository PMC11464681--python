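"""Connectivity estimation, hybrid-distance clustering, FNC tests, features."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from vwm_errnet.network import (
    HybridNetworkClustering,
    complete_linkage,
    fisher_z_fc,
    fnc_cluster_tests,
    group_mean_fc,
    hybrid_distance_matrix,
    network_fc_features,
    select_partition,
)


# ---------------------------------------------------------------------------
# Fisher-z connectivity
# ---------------------------------------------------------------------------

def test_fisher_z_matches_manual_correlation(rng):
    ts = rng.standard_normal((50, 5))
    z = np.asarray(fisher_z_fc(ts))
    for i in range(5):
        for j in range(i + 1, 5):
            a, b = ts[:, i], ts[:, j]
            r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
                np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
            assert z[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)


def test_fisher_z_perfect_anticorrelation_clipped(rng):
    x = rng.standard_normal(30)
    ts = np.column_stack([x, -x, rng.standard_normal(30)])
    with pytest.warns(UserWarning, match="clipped"):
        z = np.asarray(fisher_z_fc(ts))
    assert np.isfinite(z[0, 1]) and z[0, 1] < -10


def test_fisher_z_independent_long_series_near_zero(rng):
    ts = rng.standard_normal((20000, 3))
    z = np.asarray(fisher_z_fc(ts))
    assert np.abs(z[np.triu_indices(3, 1)]).max() < 0.05


def test_fisher_z_constant_series_names_roi():
    ts = np.column_stack([np.ones(20), np.arange(20.0)])
    with pytest.raises(ValueError, match="flat"):
        fisher_z_fc(ts, labels=["flat", "ramp"])


# ---------------------------------------------------------------------------
# hybrid distance
# ---------------------------------------------------------------------------

def _toy_group_fc(rng, n=4):
    z = rng.standard_normal((n, n))
    z = (z + z.T) / 2
    np.fill_diagonal(z, np.nan)
    return z


def test_hybrid_distance_literal_formula(rng):
    """4-ROI worked example: distances equal the literal double summation
    (self-columns excluded, each metric scaled by its maximum)."""
    F = _toy_group_fc(rng)
    C = rng.uniform(-50, 50, (4, 3))
    r = 0.95
    Ff = np.nan_to_num(F)
    n = 4
    Df = np.zeros((n, n))
    Da = np.zeros((n, n))
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            s = 0.0
            for j in range(n):
                if j in (p, q):
                    continue
                s += (Ff[p, j] - Ff[q, j]) ** 2
            Df[p, q] = s
            Da[p, q] = sum((C[p, k] - C[q, k]) ** 2 for k in range(3))
    expected = r * Df / Df.max() + (1 - r) * Da / Da.max()
    got = hybrid_distance_matrix(F, centroids=C, r=r)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_hybrid_distance_r_extremes(rng):
    F = _toy_group_fc(rng)
    C = rng.uniform(-50, 50, (4, 3))
    d1 = hybrid_distance_matrix(F, centroids=C, r=1.0)
    d0 = hybrid_distance_matrix(F, centroids=C, r=0.0)
    # r=1: pure (rescaled) functional distance, independent of anatomy
    np.testing.assert_allclose(d1, hybrid_distance_matrix(F, centroids=None, r=1.0))
    # r=0: pure (rescaled) anatomical squared Euclidean distance
    diff = C[:, None, :] - C[None, :, :]
    Da = (diff ** 2).sum(-1)
    np.testing.assert_allclose(d0, Da / Da.max(), atol=1e-12)


def test_hybrid_distance_symmetric_zero_diagonal(rng):
    D = hybrid_distance_matrix(_toy_group_fc(rng), r=0.95)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)


# ---------------------------------------------------------------------------
# complete linkage
# ---------------------------------------------------------------------------

def test_equilateral_triangle_ties():
    D = np.ones((3, 3)) - np.eye(3)
    Z = complete_linkage(D)
    np.testing.assert_allclose(Z[:, 2], [1.0, 1.0])
    assert (Z[0, 0], Z[0, 1]) == (0.0, 1.0)  # lexicographic tie rule


@pytest.mark.parametrize("seed", range(10))
def test_complete_linkage_matches_scipy(seed):
    """Random 8–12 point instances: identical merge heights to the
    independent implementation."""
    r = np.random.default_rng(seed)
    n = int(r.integers(8, 13))
    pts = r.standard_normal((n, 3))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    Z_mine = complete_linkage(D)
    Z_scipy = scipy_linkage(squareform(D, checks=False), method="complete")
    np.testing.assert_allclose(Z_mine[:, 2], Z_scipy[:, 2], rtol=1e-12)
    # identical partitions at every cut level
    from scipy.cluster.hierarchy import fcluster
    for k in (2, 3, 4):
        a = fcluster(Z_mine, k, "maxclust")
        b = fcluster(Z_scipy, k, "maxclust")
        assert adjusted_rand_score(a, b) == 1.0


def test_merge_heights_monotone(rng):
    pts = rng.standard_normal((15, 2))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    Z = complete_linkage(D)
    assert np.all(np.diff(Z[:, 2]) >= -1e-12)


def test_nan_distance_rejected():
    D = np.zeros((3, 3))
    D[0, 1] = D[1, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        complete_linkage(D)


def test_two_separated_blobs_first_cut():
    r = np.random.default_rng(0)
    pts = np.vstack([r.normal(0, 0.1, (5, 2)), r.normal(10, 0.1, (5, 2))])
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels, info = select_partition(complete_linkage(D))
    assert info["n_clusters"] == 2
    assert adjusted_rand_score(labels, [0] * 5 + [1] * 5) == 1.0


def test_select_partition_degenerate_fallback():
    D = np.ones((4, 4)) - np.eye(4)
    Z = complete_linkage(D)
    with pytest.raises(ValueError):
        select_partition(Z)
    with pytest.warns(UserWarning, match="degenerate"):
        labels, info = select_partition(Z, n_clusters_fallback=2)
    assert info["n_clusters"] == 2


def test_clustering_invariant_to_roi_order(planted_fc_small):
    mats, part = planted_fc_small
    group = group_mean_fc(mats)
    est = HybridNetworkClustering().fit(group)
    perm = np.random.default_rng(1).permutation(12)
    gp = np.asarray(group)[np.ix_(perm, perm)]
    est_p = HybridNetworkClustering().fit(pd.DataFrame(gp))
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(12)
    assert adjusted_rand_score(est.labels_, est_p.labels_[inverse]) == 1.0


def test_planted_partition_recovered(planted_fc_small):
    mats, part = planted_fc_small
    est = HybridNetworkClustering().fit(group_mean_fc(mats))
    assert est.n_clusters_ == 3
    assert adjusted_rand_score(est.labels_, part) == 1.0


def test_partition_robust_to_centroid_perturbation(planted_fc_small):
    """With r = 0.95 the 5% anatomical term tolerates noisy centroids."""
    mats, part = planted_fc_small
    group = group_mean_fc(mats)
    r = np.random.default_rng(2)
    for _ in range(5):
        coords = r.uniform(-60, 60, (12, 3))  # anatomy unrelated to communities
        est = HybridNetworkClustering().fit(group, centroids=coords)
        assert adjusted_rand_score(est.labels_, part) == 1.0


# ---------------------------------------------------------------------------
# FNC cluster tests
# ---------------------------------------------------------------------------

def _null_matrices(rng, n_sub, n_roi, scale=0.3):
    mats = []
    for _ in range(n_sub):
        z = rng.normal(0, scale, (n_roi, n_roi))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        mats.append(z)
    return mats


def test_fnc_shifted_data_all_pairs_significant(rng):
    mats = [m + 0.5 for m in _null_matrices(rng, 25, 8, scale=0.1)]
    labels = np.repeat([1, 2], 4)
    res = fnc_cluster_tests(mats, labels, random_state=0)
    assert res["significant"].all()


def test_fnc_self_pair_equals_brute_force_hotelling(rng):
    mats = _null_matrices(rng, 30, 6)
    labels = np.array([1, 1, 1, 2, 2, 2])
    res = fnc_cluster_tests(mats, labels, random_state=0)
    row = res[(res.network_a == 1) & (res.network_b == 1)].iloc[0]
    # brute force over the within-network connection set
    conns = [(0, 1), (0, 2), (1, 2)]
    Y = np.stack([np.stack([m[p, q] for p, q in conns]) for m in mats])
    S, k = Y.shape
    xbar = Y.mean(0)
    T2 = S * xbar @ np.linalg.solve(np.cov(Y.T, ddof=1), xbar)
    F = (S - k) / (k * (S - 1)) * T2
    assert row["statistic"] == pytest.approx(F, rel=1e-10)


def test_fnc_small_sample_uses_permutation(rng):
    mats = _null_matrices(rng, 5, 8)  # 5 subjects << 16 cross connections
    labels = np.repeat([1, 2], 4)
    res = fnc_cluster_tests(mats, labels, n_permutations=200, random_state=1)
    assert (res.loc[(res.network_a == 1) & (res.network_b == 2),
                    "stat_name"] == "max_t_perm").all()


def test_fnc_label_mismatch_rejected(rng):
    mats = _null_matrices(rng, 5, 6)
    with pytest.raises(ValueError, match="partition"):
        fnc_cluster_tests(mats, np.array([1, 2]))


def test_bh_fdr_matches_literal_step_up(rng):
    """The FDR step across network pairs reproduces the literal
    Benjamini–Hochberg step-up rule, checked via enumerated p-lists."""
    from statsmodels.stats.multitest import multipletests

    def literal_bh(pvals, alpha=0.05):
        m = len(pvals)
        order = np.argsort(pvals)
        thresh = alpha * (np.arange(1, m + 1)) / m
        passed = np.where(np.sort(pvals) <= thresh)[0]
        k = passed.max() + 1 if len(passed) else 0
        reject = np.zeros(m, dtype=bool)
        reject[order[:k]] = True
        return reject

    cases = [
        [0.001, 0.01, 0.02, 0.8],
        [0.04, 0.045, 0.049, 0.051],
        [0.9, 0.95, 0.99],
        [0.0001, 0.0002],
        list(rng.uniform(0, 1, 10)),
    ]
    for pv in cases:
        pv = np.asarray(pv)
        rej, *_ = multipletests(pv, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(rej, literal_bh(pv))
    assert literal_bh(np.array([0.001, 0.01, 0.02, 0.8])).sum() == 3


def test_fnc_null_type_one_error_controlled():
    """Independent null data: FDR-significant pairs are rare."""
    sig = 0
    total = 0
    for seed in range(40):
        r = np.random.default_rng(seed)
        mats = _null_matrices(r, 20, 6)
        labels = np.array([1, 1, 1, 2, 2, 2])
        res = fnc_cluster_tests(mats, labels, random_state=seed)
        sig += int(res["significant"].sum())
        total += len(res)
    assert sig / total <= 0.08


# ---------------------------------------------------------------------------
# network features
# ---------------------------------------------------------------------------

def _feature_toy():
    z = np.full((6, 6), np.nan)
    vals = iter(np.arange(15.0))
    for i in range(6):
        for j in range(i + 1, 6):
            z[i, j] = z[j, i] = next(vals)
    return z


def test_features_constant_matrix():
    z = np.full((6, 6), 0.7)
    np.fill_diagonal(z, np.nan)
    feats = network_fc_features(z, np.array([1, 1, 2, 2, 3, 3]))
    assert np.allclose(feats.to_numpy(dtype=float), 0.7)


def test_features_hand_computed_means():
    z = _feature_toy()
    labels = np.array([1, 1, 1, 2, 2, 3])
    feats = network_fc_features(z, labels)
    assert feats["fc_w_N1"] == pytest.approx(np.mean([z[0, 1], z[0, 2], z[1, 2]]))
    assert feats["fc_w_N2"] == pytest.approx(z[3, 4])
    assert np.isnan(feats["fc_w_N3"])  # singleton network
    assert feats["fc_b_N2_N3"] == pytest.approx(np.mean([z[3, 5], z[4, 5]]))


def test_features_invariant_to_network_relabeling():
    z = _feature_toy()
    a = network_fc_features(z, np.array([1, 1, 1, 2, 2, 2]))
    b = network_fc_features(z, np.array([2, 2, 2, 1, 1, 1]))
    assert a["fc_w_N1"] == b["fc_w_N2"]
    assert a["fc_b_N1_N2"] == b["fc_b_N1_N2"]


def test_features_conserve_grand_mean(rng):
    """Pair-count-weighted mean of all features equals the off-diagonal mean."""
    z = rng.standard_normal((10, 10))
    z = (z + z.T) / 2
    np.fill_diagonal(z, np.nan)
    labels = rng.integers(1, 4, 10)
    while len(np.unique(labels)) < 3:
        labels = rng.integers(1, 4, 10)
    feats = network_fc_features(z, labels)
    counts = {}
    nets = np.unique(labels)
    for i, ni in enumerate(nets):
        for nj in nets[i:]:
            a, b = (labels == ni).sum(), (labels == nj).sum()
            cnt = a * (a - 1) // 2 if ni == nj else a * b
            name = f"fc_w_N{ni}" if ni == nj else f"fc_b_N{ni}_N{nj}"
            counts[name] = cnt
    num = sum(feats[k] * c for k, c in counts.items() if c > 0)
    den = sum(c for c in counts.values())
    grand = np.nanmean(z[np.triu_indices(10, 1)])
    assert num / den == pytest.approx(grand, abs=1e-12)
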