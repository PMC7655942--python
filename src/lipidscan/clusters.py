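"""Correlation-based lipid clustering: Spearman, complete linkage, hybrid tree cut.

Lipid panels are strongly co-linear (species sharing synthetic pathways or
chain compositions track each other across individuals).  For risk-model
feature selection those co-linear groups must be treated as units, so the
pipeline clusters species by Spearman correlation distance d = 1 - rho
(signed: only positively interchangeable species should share a cluster),
complete-linkage hierarchical clustering, and a dynamic hybrid tree cut:

* stage 1 walks the dendrogram top-down and keeps a branch as a cluster
  when it is large enough (``min_cluster_size``), tight enough (mean
  within-branch distance below a core-scatter ceiling), and does not
  itself contain well-separated sub-branches (merge-height gap below a
  minimum gap).  The ceiling and gap are controlled by ``deep_split``
  (0-4; higher splits more aggressively).
* stage 2 assigns each leftover singleton to the nearest detected cluster
  when its average distance to that cluster's members falls below the
  height at which the cluster merges into the rest of the tree; otherwise
  it stays unassigned (label 0).

Clusters are relabelled 1..K by decreasing size.  The implementation
follows the dynamic hybrid algorithm's contract; it is not intended to be
byte-identical to any particular external implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "ClusterAssignment",
    "spearman_matrix",
    "correlation_distance",
    "complete_linkage_tree",
    "dynamic_hybrid_cut",
    "representative_ranking",
]

# deep_split (0..4) -> maximum core scatter as a fraction of the cut height
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class ClusterAssignment:
    """lipid -> cluster id (positive int; 0 = unassigned)."""

    labels: pd.Series  # int labels indexed by lipid name
    n_clusters: int
    min_cluster_size: int
    deep_split: int
    distance: str = "1 - spearman rho"

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation across columns (average ranks for ties)."""
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    X = matrix.to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    if const.any():
        raise ValueError(
            f"constant column(s): {list(matrix.columns[const])} — correlation undefined"
        )
    ranks = np.apply_along_axis(rankdata, 0, X)
    corr = np.corrcoef(ranks, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


def correlation_distance(corr: pd.DataFrame) -> pd.DataFrame:
    """Signed correlation distance d = 1 - rho (anti-correlated pairs are far)."""
    d = 1.0 - corr
    d = (d + d.T) / 2.0
    np.fill_diagonal(d.values, 0.0)
    return d


def complete_linkage_tree(distance: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Agglomerative complete-linkage dendrogram (scipy linkage matrix)."""
    D = np.asarray(distance, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return linkage(squareform(D, checks=False), method="complete")


def dynamic_hybrid_cut(
    Z: np.ndarray,
    distance: pd.DataFrame | np.ndarray,
    min_cluster_size: int = 2,
    deep_split: int = 1,
) -> ClusterAssignment:
    """Cut a complete-linkage dendrogram with the dynamic hybrid procedure."""
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    if isinstance(distance, pd.DataFrame):
        names = list(distance.columns)
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        names = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]

    if min_cluster_size > n:
        warnings.warn(
            f"min_cluster_size {min_cluster_size} exceeds panel size {n}; "
            "all lipids left unassigned",
            stacklevel=2,
        )
        labels = pd.Series(0, index=pd.Index(names), dtype=int)
        return ClusterAssignment(labels, 0, min_cluster_size, deep_split)

    heights = Z[:, 2]
    max_h = float(heights.max()) if len(heights) else 0.0
    cut_height = 0.99 * max_h
    mcs = _MAX_CORE_SCATTER[deep_split]
    max_scatter = mcs * cut_height
    min_gap = (1.0 - mcs) * 0.75 * cut_height

    children = Z[:, :2].astype(int)

    member_cache: dict[int, np.ndarray] = {}

    def members(node: int) -> np.ndarray:
        if node < n:
            return np.array([node])
        if node not in member_cache:
            l, r = children[node - n]
            member_cache[node] = np.concatenate([members(l), members(r)])
        return member_cache[node]

    def height(node: int) -> float:
        return 0.0 if node < n else float(heights[node - n])

    def scatter(idx: np.ndarray) -> float:
        if idx.size < 2:
            return 0.0
        sub = D[np.ix_(idx, idx)]
        m = idx.size
        return float(sub.sum() / (m * (m - 1)))

    clusters: list[tuple[np.ndarray, float]] = []  # (member idx, merging threshold)
    pool: list[int] = []

    def recurse(node: int, parent_height: float) -> None:
        idx = members(node)
        if idx.size < min_cluster_size:
            pool.extend(idx.tolist())
            return
        h = height(node)
        if h <= cut_height:
            l, r = children[node - n]
            has_distinct_subbranch = any(
                members(c).size >= min_cluster_size and (h - height(c)) >= min_gap
                for c in (l, r)
            )
            if not has_distinct_subbranch and scatter(idx) <= max_scatter:
                clusters.append((idx, parent_height))
                return
        l, r = children[node - n]
        recurse(l, h)
        recurse(r, h)

    root = n + len(heights) - 1 if len(heights) else 0
    recurse(root, max_h)

    labels_arr = np.zeros(n, dtype=int)
    for k, (idx, _) in enumerate(clusters, start=1):
        labels_arr[idx] = k

    # stage 2: attach singletons whose average distance to a cluster's
    # members falls below that cluster's merging threshold
    for i in pool:
        best_k, best_d = 0, np.inf
        for k, (idx, thr) in enumerate(clusters, start=1):
            avg = float(D[i, idx].mean())
            if avg < thr and avg < best_d:
                best_k, best_d = k, avg
        labels_arr[i] = best_k

    # relabel 1..K by decreasing size (stable on ties)
    out = np.zeros(n, dtype=int)
    ids, counts = np.unique(labels_arr[labels_arr > 0], return_counts=True)
    order = sorted(range(len(ids)), key=lambda j: (-counts[j], ids[j]))
    for new, j in enumerate(order, start=1):
        out[labels_arr == ids[j]] = new

    labels = pd.Series(out, index=pd.Index(names), dtype=int)
    return ClusterAssignment(labels, int(out.max(initial=0)), min_cluster_size, deep_split)


def representative_ranking(
    frequencies: pd.Series,
    assignment: ClusterAssignment,
    tiebreak: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank clusters by summed member frequency; pick each cluster's champion.

    ``frequencies`` counts how often each lipid was incorporated into
    cross-validated training models.  Unassigned lipids (label 0) are
    treated as singleton clusters.  Cluster ties are broken by the best
    (lowest) value of ``tiebreak`` among members (e.g. mean within-model
    AIC rank), then lexicographically by representative name; member ties
    for the representative use the same rule.
    """
    if (frequencies < 0).any():
        raise ValueError("frequencies must be non-negative")
    labels = assignment.labels.reindex(frequencies.index)
    if labels.isna().any():
        missing = list(frequencies.index[labels.isna()])
        raise KeyError(f"lipids without cluster assignment: {missing}")
    tb = (
        tiebreak.reindex(frequencies.index).fillna(np.inf)
        if tiebreak is not None
        else pd.Series(np.inf, index=frequencies.index)
    )

    groups: dict[object, list[str]] = {}
    next_singleton = -1
    for lipid, lab in labels.items():
        key: object = int(lab)
        if lab == 0:
            key = ("singleton", next_singleton)
            next_singleton -= 1
        groups.setdefault(key, []).append(lipid)

    rows = []
    for key, members in groups.items():
        f = frequencies[members]
        total = float(f.sum())
        rep = sorted(members, key=lambda m: (-f[m], tb[m], m))[0]
        rows.append(
            {
                "cluster": key if isinstance(key, int) else 0,
                "frequency": total,
                "representative": rep,
                "size": len(members),
                "_tb": float(tb[members].min()),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["frequency", "_tb", "representative"],
        ascending=[False, True, True],
        kind="stable",
    ).drop(columns="_tb")
    return out.reset_index(drop=True)
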