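"""Intrinsic-network identification from ROI-to-ROI connectivity.

ROI time series become Fisher-z connectivity matrices; the group-average
matrix drives an agglomerative complete-linkage clustering under a hybrid
distance that mixes functional-profile dissimilarity with anatomical
proximity:

    d(p, q) = r · Σ_j (F̄_pj − F̄_qj)²  +  (1 − r) · Σ_k (C_pk − C_qk)²

with r = 0.95 by default. The two squared-distance matrices are each
rescaled by their own maximum before mixing — the anatomical term is in mm²
and would otherwise dominate the z² functional term. The partition is read
off the dendrogram at the largest relative jump in linkage distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster
from sklearn.base import BaseEstimator, ClusterMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_z_fc",
    "group_mean_fc",
    "hybrid_distance_matrix",
    "complete_linkage",
    "select_partition",
    "HybridNetworkClustering",
    "fnc_cluster_tests",
    "network_fc_features",
]


# ---------------------------------------------------------------------------
# first level: connectivity estimation
# ---------------------------------------------------------------------------

def fisher_z_fc(timeseries, labels=None) -> pd.DataFrame:
    """Fisher-transformed Pearson correlation between ROI time series.

    ``timeseries`` is (n_timepoints, n_rois). Correlations with |r| at 1 are
    clipped to 1 - 1e-12 with a warning so z stays finite. The diagonal
    (self-correlation) is undefined and stored as NaN.
    """
    ts = np.asarray(timeseries, dtype=float)
    if isinstance(timeseries, pd.DataFrame) and labels is None:
        labels = list(timeseries.columns)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a (n_timepoints >= 3, n_rois) array")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.argmax(sd == 0))
        name = labels[idx] if labels is not None else f"column {idx}"
        raise ValueError(f"constant time series for ROI {name!r}")
    r = np.corrcoef(ts.T)
    off = ~np.eye(len(r), dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0 - 1e-12):
        warnings.warn("correlation at ±1 clipped before Fisher transform")
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, np.nan)
    if labels is None:
        labels = [f"roi{i + 1:02d}" for i in range(z.shape[0])]
    return pd.DataFrame(z, index=labels, columns=labels)


def group_mean_fc(matrices) -> pd.DataFrame:
    """Across-subject mean of Fisher-z matrices (averaged on the z scale)."""
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices given")
    ref = mats[0]
    stack = np.stack([np.asarray(m, dtype=float) for m in mats])
    mean = stack.mean(axis=0)
    if isinstance(ref, pd.DataFrame):
        return pd.DataFrame(mean, index=ref.index, columns=ref.columns)
    return pd.DataFrame(mean)


# ---------------------------------------------------------------------------
# hybrid distance
# ---------------------------------------------------------------------------

def hybrid_distance_matrix(group_fc, centroids=None, r: float = 0.95) -> np.ndarray:
    """Pairwise hybrid functional+anatomical squared distances.

    Functional profiles are rows of the group-mean FC matrix; the two
    self-connectivity entries (columns p and q, undefined on the z scale)
    are excluded from each pair's profile sum. Both metric matrices are
    divided by their own maximum before the r-weighted combination.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    F = np.asarray(group_fc, dtype=float)
    n = F.shape[0]
    if F.shape != (n, n):
        raise ValueError("group FC must be square")
    Ff = np.nan_to_num(F, nan=0.0)
    Df = np.zeros((n, n))
    for p in range(n):
        for q in range(p + 1, n):
            diff2 = (Ff[p] - Ff[q]) ** 2
            # self-columns p and q are undefined on the z scale -> excluded
            Df[p, q] = Df[q, p] = diff2.sum() - diff2[p] - diff2[q]
    if centroids is not None:
        C = np.asarray(centroids, dtype=float)
        if C.shape != (n, 3):
            raise ValueError(f"centroids must be (n_rois, 3), got {C.shape}")
        diff = C[:, None, :] - C[None, :, :]
        Da = (diff**2).sum(axis=-1)
    else:
        Da = np.zeros((n, n))
    if Df.max() > 0:
        Df = Df / Df.max()
    if Da.max() > 0:
        Da = Da / Da.max()
    return r * Df + (1.0 - r) * Da


# ---------------------------------------------------------------------------
# complete-linkage agglomeration
# ---------------------------------------------------------------------------

def complete_linkage(distance: np.ndarray) -> np.ndarray:
    """Agglomerative complete-linkage clustering of a distance matrix.

    Inter-cluster distance is the maximum pairwise member distance; the pair
    with the smallest distance merges at each step, ties broken by the
    lexicographically lowest (id-a, id-b) pair using scipy cluster ids
    (originals 0..n-1, then n+k for the k-th merge). Returns a scipy-format
    linkage matrix (id-a, id-b, height, member count).
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(D)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")

    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    # dc[(a, b)] with a < b: current complete-linkage distance
    dc = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    Z = np.zeros((n - 1, 4))
    for k in range(n - 1):
        best = min(dc.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        new = n + k
        members = active.pop(a) + active.pop(b)
        for c in list(active):
            da = dc.pop((min(a, c), max(a, c)))
            db = dc.pop((min(b, c), max(b, c)))
            dc[(min(c, new), max(c, new))] = max(da, db)
        dc.pop((a, b))
        active[new] = members
        Z[k] = [a, b, h, len(members)]
    return Z


def select_partition(linkage_matrix: np.ndarray, n_clusters: int | None = None,
                     method: str = "ratio", n_clusters_fallback: int | None = None):
    """Cut the dendrogram at the elbow of the merge-height profile.

    ``method='ratio'`` (default) places the cut at the largest relative jump
    ``h[i+1]/h[i]`` between successive merge heights, which is scale-free and
    robust to linkage heights growing with cluster size; ``method='gap'``
    uses the largest absolute difference. A degenerate profile (no usable
    jump) falls back to a user-supplied ``n_clusters`` with a warning.

    Returns ``(labels, info)`` where labels are 1..K per leaf and ``info``
    carries the gap profile and cut index.
    """
    Z = np.asarray(linkage_matrix, dtype=float)
    m = Z.shape[0] + 1
    h = Z[:, 2]
    info = {"heights": h}
    if n_clusters is None:
        tiny = 1e-12 * max(h[-1], 1.0)
        if method == "ratio":
            with np.errstate(divide="ignore", invalid="ignore"):
                prof = h[1:] / np.maximum(h[:-1], tiny)
        elif method == "gap":
            prof = np.diff(h)
        else:
            raise ValueError(f"unknown elbow method {method!r}")
        info["gap_profile"] = prof
        degenerate = (len(prof) == 0 or np.all(~np.isfinite(prof))
                      or np.ptp(h) <= tiny)
        if degenerate:
            if n_clusters_fallback is None:
                raise ValueError(
                    "no elbow in linkage heights and no fallback n_clusters given")
            warnings.warn("degenerate linkage-height profile (no elbow); "
                          "falling back to the requested cluster count")
            n_clusters = int(n_clusters_fallback)
        else:
            cut = int(np.argmax(prof))
            n_clusters = m - (cut + 1)
            info["cut_index"] = cut
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel deterministically by first-member order
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    labels = np.array([order[lab] for lab in labels])
    info["n_clusters"] = int(n_clusters)
    return labels, info


class HybridNetworkClustering(ClusterMixin, BaseEstimator):
    """Complete-linkage network identification from a group FC matrix.

    Parameters
    ----------
    r : float
        Weight of the functional metric in the hybrid distance (0.95 gives
        anatomy a 5% say).
    n_clusters : int or None
        Fixed cluster count; None selects it at the largest relative jump in
        linkage distance.
    elbow : {"ratio", "gap"}
        Elbow definition used when ``n_clusters`` is None.

    Attributes
    ----------
    labels_ : (n_rois,) int, networks numbered 1..K in first-ROI order
    linkage_ : scipy-format merge list
    heights_ : merge heights
    n_clusters_ : int
    distance_ : the hybrid distance matrix
    """

    def __init__(self, r: float = 0.95, n_clusters: int | None = None,
                 elbow: str = "ratio", n_clusters_fallback: int | None = None):
        self.r = r
        self.n_clusters = n_clusters
        self.elbow = elbow
        self.n_clusters_fallback = n_clusters_fallback

    def fit(self, X, y=None, centroids=None):
        X = pd.DataFrame(X)
        D = hybrid_distance_matrix(X, centroids=centroids, r=self.r)
        Z = complete_linkage(D)
        labels, info = select_partition(
            Z, n_clusters=self.n_clusters, method=self.elbow,
            n_clusters_fallback=self.n_clusters_fallback)
        self.distance_ = D
        self.linkage_ = Z
        self.heights_ = Z[:, 2]
        self.labels_ = labels
        self.n_clusters_ = info["n_clusters"]
        self.gap_profile_ = info.get("gap_profile")
        self.roi_labels_ = list(X.index)
        return self

    def partition_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"roi": self.roi_labels_, "network": self.labels_})


# ---------------------------------------------------------------------------
# cluster-level statistics and features
# ---------------------------------------------------------------------------

def _pair_connections(labels: np.ndarray, i: int, j: int):
    """Index pairs (p, q), p < q, connecting networks i and j."""
    a = np.where(labels == i)[0]
    b = np.where(labels == j)[0]
    if i == j:
        return [(p, q) for ii, p in enumerate(a) for q in a[ii + 1:]]
    return [(min(p, q), max(p, q)) for p in a for q in b]


def fnc_cluster_tests(matrices, labels, alpha_cluster: float = 0.05,
                      alpha_conn: float = 0.05, n_permutations: int = 2000,
                      random_state=None) -> pd.DataFrame:
    """Network-pair tests that mean connectivity differs from zero.

    For every unordered network pair (including self-pairs) the subject ×
    connection matrix enters a multivariate one-sample test: Hotelling's T²
    when subjects exceed the connection count by at least 2, otherwise an
    omnibus max-|t| statistic with a sign-flip permutation p-value.
    Benjamini–Hochberg FDR is applied across pairs; suprathreshold
    connections are listed from per-connection one-sample t-tests at
    uncorrected ``alpha_conn``.
    """
    labels = np.asarray(labels)
    mats = [np.asarray(m, dtype=float) for m in matrices]
    n_rois = mats[0].shape[0]
    if len(labels) != n_rois:
        raise ValueError("partition length does not match matrix dimension")
    roi_names = (list(matrices[0].index)
                 if isinstance(matrices[0], pd.DataFrame)
                 else [f"roi{i + 1:02d}" for i in range(n_rois)])
    stack = np.stack(mats)  # (S, n, n)
    S = stack.shape[0]
    rng = np.random.default_rng(random_state)
    networks = np.unique(labels)
    rows = []
    for ii, ni in enumerate(networks):
        for nj in networks[ii:]:
            conns = _pair_connections(labels, ni, nj)
            if not conns:
                continue  # singleton self-pair: no connections to test
            Y = np.stack([stack[:, p, q] for p, q in conns], axis=1)  # (S, k)
            k = Y.shape[1]
            xbar = Y.mean(axis=0)
            if S >= k + 2:
                cov = np.cov(Y.T, ddof=1).reshape(k, k)
                t2 = S * xbar @ np.linalg.solve(cov, xbar)
                fstat = (S - k) / (k * (S - 1)) * t2
                p = float(stats.f.sf(fstat, k, S - k))
                statistic, stat_name, df = float(fstat), "hotelling_F", (k, S - k)
            else:
                tvals = xbar / (Y.std(axis=0, ddof=1) / np.sqrt(S))
                obs = float(np.max(np.abs(tvals)))
                signs = rng.choice([-1.0, 1.0], size=(n_permutations, S))
                null = np.empty(n_permutations)
                for b in range(n_permutations):
                    Yb = Y * signs[b][:, None]
                    tb = Yb.mean(0) / (Yb.std(0, ddof=1) / np.sqrt(S))
                    null[b] = np.max(np.abs(tb))
                p = float((1 + np.sum(null >= obs)) / (1 + n_permutations))
                statistic, stat_name, df = obs, "max_t_perm", (k, S - 1)
            tt = stats.ttest_1samp(Y, 0.0, axis=0)
            supra = [f"{roi_names[p_]}--{roi_names[q_]}"
                     for (p_, q_), pc in zip(conns, np.atleast_1d(tt.pvalue))
                     if pc < alpha_conn]
            rows.append(dict(network_a=int(ni), network_b=int(nj),
                             n_connections=k, statistic=statistic,
                             stat_name=stat_name, df1=df[0], df2=df[1],
                             p=p, suprathreshold=supra,
                             mean_z=float(xbar.mean())))
    res = pd.DataFrame(rows)
    rej, q, *_ = multipletests(res["p"], alpha=alpha_cluster, method="fdr_bh")
    res["q_fdr"] = q
    res["significant"] = rej
    return res


def network_fc_features(matrix, labels) -> pd.Series:
    """Average within- and between-network connectivity for one subject.

    FC_W(N) averages all unordered ROI pairs inside network N (NaN for
    singletons); FC_B(N, N') averages every cross pair. All connections
    enter regardless of any threshold.
    """
    z = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    networks = np.unique(labels)
    out = {}
    for ii, ni in enumerate(networks):
        for nj in networks[ii:]:
            conns = _pair_connections(labels, ni, nj)
            name = (f"fc_w_N{ni}" if ni == nj else f"fc_b_N{ni}_N{nj}")
            out[name] = (np.mean([z[p, q] for p, q in conns])
                         if conns else np.nan)
    return pd.Series(out)


def network_fc_feature_table(matrices, labels, subjects=None) -> pd.DataFrame:
    """Feature rows for a list of per-subject matrices."""
    rows = []
    for s, m in enumerate(matrices):
        feats = network_fc_features(m, labels)
        feats["subject"] = subjects[s] if subjects is not None else f"sub-{s + 1:03d}"
        rows.append(feats)
    df = pd.DataFrame(rows)
    return df[["subject"] + [c for c in df.columns if c != "subject"]]
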