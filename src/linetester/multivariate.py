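"""Trait correlations and hierarchical clustering of genotypes.

Genotype × trait mean matrices are z-scored per trait (traits are measured in
incommensurable units), then clustered on Euclidean distances.  Six
agglomerative linkages are supported; Ward is the squared-distance
Lance–Williams variant (ward.D2-equivalent), and "flexible" is flexible-beta
linkage with beta = -0.25.  Method quality is compared through the
agglomerative coefficient, the number of clusters is chosen by a vote of
internal validity indices, and two dendrograms over the same genotypes can be
compared through a leaf-position entanglement score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

LINKAGE_METHODS = ("single", "complete", "average", "weighted", "ward", "flexible")

#: Flexible-beta (Lance–Williams) shape parameter; -0.25 is the classical default.
FLEXIBLE_BETA = -0.25


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values and marks."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int


@dataclass
class ClusterModel:
    """A fitted agglomerative clustering of genotypes.

    ``linkage`` is a scipy-format merge table (n-1 rows of
    ``[left, right, height, size]``) over ``labels``.
    """

    method: str
    labels: list[str]
    linkage: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Cluster assignments (1..k) at k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def quote(label: str) -> str:
            if any(c in label for c in " (),:;'[]"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{quote(self.labels[node.id])}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column to mean 0, sample standard deviation 1 (ddof = 1)."""
    mat = matrix.astype(float)
    sd = mat.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant trait column(s), cannot standardize: {constant}")
    return (mat - mat.mean()) / sd


def pearson_matrix(matrix: pd.DataFrame) -> CorrelationMatrix:
    """All-pairs Pearson correlation with t-based two-sided p on n-2 df."""
    mat = matrix.astype(float)
    n = len(mat)
    if n < 3:
        raise ValueError("need at least 3 rows for correlation p-values")
    if (mat.std(ddof=1) == 0).any():
        bad = mat.columns[mat.std(ddof=1) == 0].tolist()
        raise ValueError(f"degenerate (constant) column(s): {bad}")
    r = mat.corr(method="pearson")
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rv * np.sqrt((n - 2) / np.clip(1 - rv**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    np.fill_diagonal(p, 0.0)
    pdf = pd.DataFrame(p, index=r.index, columns=r.columns)
    marks = pdf.map(lambda v: "**" if v <= 0.01 else ("*" if v <= 0.05 else ""))
    np.fill_diagonal(marks.values, "")
    return CorrelationMatrix(r=r, p=pdf, stars=marks, n=n)


def _flexible_linkage(dist: np.ndarray, beta: float) -> np.ndarray:
    """Naive Lance–Williams agglomeration for flexible-beta linkage.

    Update: d(k, ij) = a*d(k,i) + a*d(k,j) + beta*d(i,j), a = (1-beta)/2.
    Returns a scipy-format linkage matrix.
    """
    d = squareform(dist).astype(float)
    n = d.shape[0]
    alpha = (1.0 - beta) / 2.0
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    next_id = n
    Z = np.zeros((n - 1, 4))
    # work on an expanding distance dict keyed by cluster id
    dd: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dd[(i, j)] = d[i, j]

    def get(a: int, b: int) -> float:
        return dd[(a, b)] if a < b else dd[(b, a)]

    for step in range(n - 1):
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                v = get(a, b)
                if best is None or v < best[0]:
                    best = (v, a, b)
        h, a, b = best
        for k in active:
            if k in (a, b):
                continue
            dd[tuple(sorted((k, next_id)))] = (
                alpha * get(k, a) + alpha * get(k, b) + beta * h
            )
        Z[step] = [min(a, b), max(a, b), h, sizes[a] + sizes[b]]
        sizes[next_id] = sizes[a] + sizes[b]
        active.remove(a)
        active.remove(b)
        active.append(next_id)
        next_id += 1
    return Z


def hcluster(z_matrix: pd.DataFrame, method: str = "ward") -> ClusterModel:
    """Agglomerative clustering of the rows of a (standardized) matrix.

    Euclidean distances throughout.  ``method`` is one of
    :data:`LINKAGE_METHODS`; ``ward`` operates on squared distances with
    heights reported back on the distance scale.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {LINKAGE_METHODS}")
    mat = z_matrix.astype(float)
    if len(mat) < 2:
        raise ValueError("need at least 2 rows to cluster")
    if mat.isna().any().any():
        raise ValueError("input matrix contains NaN")
    if method == "flexible":
        Z = _flexible_linkage(pdist(mat.to_numpy(), metric="euclidean"), FLEXIBLE_BETA)
    else:
        Z = hierarchy.linkage(mat.to_numpy(), method=method, metric="euclidean")
    return ClusterModel(method=method, labels=list(mat.index), linkage=Z)


def agglomerative_coefficient(model: ClusterModel) -> float:
    """Mean over objects of 1 - h_first/h_final.

    ``h_first(i)`` is the height at which object i first merges into a
    cluster and ``h_final`` the height of the last merge; values near 1
    indicate strong clustering structure.
    """
    n = model.n
    if n < 2:
        raise ValueError("need at least 2 objects")
    h_final = float(model.linkage[-1, 2])
    if h_final == 0.0:
        return 0.0
    h_first = np.empty(n)
    seen = np.zeros(n, dtype=bool)
    for left, right, height, _ in model.linkage:
        for idx in (int(left), int(right)):
            if idx < n and not seen[idx]:
                h_first[idx] = height
                seen[idx] = True
    return float(np.mean(1.0 - h_first / h_final))


_INDEX_FUNCS = {
    "silhouette": (silhouette_score, max),
    "calinski_harabasz": (calinski_harabasz_score, max),
    "davies_bouldin": (davies_bouldin_score, min),
}


def select_k(
    z_matrix: pd.DataFrame,
    k_range: range | list[int] = range(2, 6),
    indices: tuple[str, ...] = ("silhouette", "calinski_harabasz", "davies_bouldin"),
) -> tuple[int, dict[str, int]]:
    """Choose the number of clusters by majority vote of internal indices.

    Each index scores Ward partitions over ``k_range`` and votes for its
    optimum; the majority wins, ties broken toward the smaller k.  Returns
    ``(k, votes)`` with the per-index votes.
    """
    if not indices:
        raise ValueError("at least one index is required")
    unknown = [i for i in indices if i not in _INDEX_FUNCS]
    if unknown:
        raise ValueError(f"unknown indices {unknown}; known: {sorted(_INDEX_FUNCS)}")
    ks = sorted(k_range)
    n = len(z_matrix)
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    model = hcluster(z_matrix, "ward")
    X = z_matrix.to_numpy(dtype=float)
    parts = {k: model.cut(k).to_numpy() for k in ks}
    votes: dict[str, int] = {}
    for name in indices:
        func, pick = _INDEX_FUNCS[name]
        scores = {k: func(X, parts[k]) for k in ks if len(set(parts[k])) == k}
        if pick is max:  # prefer smaller k on exact ties
            best = max(scores, key=lambda k: (scores[k], -k))
        else:
            best = min(scores, key=lambda k: (scores[k], k))
        votes[name] = best
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    winner = min(k for k, c in counts.items() if c == top)
    return winner, votes


def cluster_summary(assignments: pd.Series, matrix: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-cluster means of the raw (unstandardized) trait values."""
    common = assignments.index.intersection(matrix.index)
    if len(common) != len(matrix):
        raise ValueError("assignments do not cover every genotype")
    counts = assignments.value_counts()
    if (counts == 0).any():
        raise ValueError("empty cluster in assignments")
    out = matrix.groupby(assignments).mean()
    out.index.name = "cluster"
    return out


def entanglement(
    model_a: ClusterModel, model_b: ClusterModel, shared_labels: list[str] | None = None
) -> float:
    """Leaf-position entanglement between two dendrograms over the same labels.

    0 means identical leaf orderings; 1 means one ordering is the exact
    reversal of the other (the maximal total displacement).  Computed as the
    sum of absolute leaf-position differences divided by its maximum,
    ``floor(n**2 / 2)``.
    """
    if set(model_a.labels) != set(model_b.labels):
        raise ValueError("dendrograms must share an identical label set")
    order_a = model_a.leaf_order()
    order_b = model_b.leaf_order()
    labels = shared_labels if shared_labels is not None else order_a
    pos_a = {g: i for i, g in enumerate(order_a)}
    pos_b = {g: i for i, g in enumerate(order_b)}
    n = len(order_a)
    total = sum(abs(pos_a[g] - pos_b[g]) for g in labels)
    max_total = n * n // 2
    return total / max_total if max_total else 0.0


def heatmap_export(
    z_matrix: pd.DataFrame, method: str = "ward"
) -> dict[str, object]:
    """Standardized matrix plus row/column dendrogram orders (heatmap data).

    Returns the matrix reordered by genotype and trait dendrograms, together
    with both orders and both models — everything a clustered-heatmap
    renderer needs, without any drawing.
    """
    rows = hcluster(z_matrix, method)
    cols = hcluster(z_matrix.T, method)
    row_order = rows.leaf_order()
    col_order = cols.leaf_order()
    return {
        "matrix": z_matrix.loc[row_order, col_order],
        "row_order": row_order,
        "col_order": col_order,
        "row_model": rows,
        "col_model": cols,
    }
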