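"""Product-matrix clustering into coexpressed metabolic subpathways.

The clustering substrate is the elementwise product of the gene coflux
matrix and the non-negative-clipped coexpression matrix: a pair scores high
only when the genes are both flux-coupled and coexpressed.  Average-linkage
hierarchical clustering runs on the dissimilarity 1 - product, and clusters
are extracted with an adaptive dendrogram cut driven by two parameters:
``deep_split`` (0-4, higher = more aggressive splitting) and
``min_cluster_size``.  Two presets mirror common practice: stringent
(deep_split=2, min_cluster_size=3) and relaxed (deep_split=3,
min_cluster_size=6).  Cluster quality is the mean silhouette score (MSS) of
member genes on the same dissimilarity.

The cut is this package's own top-down variant of the dynamic hybrid
tree-cut idea: leaves joining the tree above an absolute outlier height are
left unassigned; below it, a branch splits into its two children only when
both would form distinct clusters — large enough, internally tight (core
scatter) and well separated from the join (gap) — with the scatter/gap
thresholds mapped from ``deep_split`` as in the reference hybrid method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .coexpression import CoexpressionMatrix
from .coflux import CofluxMatrix

STRINGENT = {"deep_split": 2, "min_cluster_size": 3}
RELAXED = {"deep_split": 3, "min_cluster_size": 6}

# deep_split in 0..4 -> maximum normalized core scatter of an acceptable
# branch; the minimum gap is 3/4 of the complement (reference mapping).
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class ProductMatrix:
    values: pd.DataFrame  # genes x genes symmetric in [0, 1]
    n_missing_coexpr: int = 0

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class ClusterSet:
    labels: pd.Series  # gene -> cluster id; 0 = unassigned
    params: dict
    mss: dict[int, float] = field(default_factory=dict)
    silhouette: pd.Series | None = None

    @property
    def ranking(self) -> list[int]:
        return [k for k, _ in sorted(self.mss.items(), key=lambda kv: -kv[1])]

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])

    @property
    def n_clusters(self) -> int:
        return int((pd.unique(self.labels) > 0).sum())


def product_matrix(
    coflux: CofluxMatrix, coexpr: CoexpressionMatrix
) -> ProductMatrix:
    """Elementwise coflux x max(coexpression, 0) on the shared gene set.

    Missing coexpression entries count as 0 (no information, no edge).
    """
    shared = sorted(set(coflux.genes) & set(coexpr.genes))
    if not shared:
        raise ValueError("coflux and coexpression matrices share no genes")
    cf = coflux.values.loc[shared, shared].to_numpy(dtype=float)
    ce = coexpr.values.loc[shared, shared].to_numpy(dtype=float)
    n_missing = int(np.isnan(ce).sum())
    ce = np.clip(np.nan_to_num(ce, nan=0.0), 0.0, 1.0)
    prod = cf * ce
    prod = (prod + prod.T) / 2.0
    np.fill_diagonal(prod, cf.diagonal() * np.clip(np.diag(ce), 0, 1))
    return ProductMatrix(
        values=pd.DataFrame(prod, index=shared, columns=shared),
        n_missing_coexpr=n_missing,
    )


# ------------------------------------------------------------ adaptive cut


def _subtree_stats(Z: np.ndarray, n: int):
    """Leaves, top height, and mean internal merge height per node."""
    leaves: list[list[int]] = [[i] for i in range(n)] + [None] * (n - 1)
    height = np.zeros(2 * n - 1)
    scatter = np.zeros(2 * n - 1)  # mean merge height within the subtree
    n_merges = np.zeros(2 * n - 1)
    sum_h = np.zeros(2 * n - 1)
    for k in range(n - 1):
        a, b, h = int(Z[k, 0]), int(Z[k, 1]), Z[k, 2]
        node = n + k
        leaves[node] = leaves[a] + leaves[b]
        height[node] = h
        sum_h[node] = sum_h[a] + sum_h[b] + h
        n_merges[node] = n_merges[a] + n_merges[b] + 1
        scatter[node] = sum_h[node] / n_merges[node]
    return leaves, height, scatter


def cluster_product(
    pm: ProductMatrix,
    deep_split: int = 2,
    min_cluster_size: int = 3,
    outlier_height: float = 0.99,
) -> ClusterSet:
    """Average-linkage clustering of 1 - product with the adaptive cut.

    Leaves merging only above ``outlier_height`` stay unassigned (label 0),
    as do members of branches smaller than ``min_cluster_size``.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    genes = list(pm.genes)
    n = len(genes)
    params = {"deep_split": deep_split, "min_cluster_size": min_cluster_size}
    if n < min_cluster_size or n < 2:
        return ClusterSet(
            labels=pd.Series(0, index=genes, dtype=int), params=params
        )
    D = 1.0 - pm.values.to_numpy(dtype=float)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    leaves, height, scatter = _subtree_stats(Z, n)
    hmax = float(Z[:, 2].max())
    if hmax <= 0:
        labels = pd.Series(1, index=genes, dtype=int)
        return ClusterSet(labels=labels, params=params)

    max_scatter = _MAX_CORE_SCATTER[deep_split]
    min_gap = 0.75 * (1.0 - max_scatter)

    def distinct(child: int, parent_h: float) -> bool:
        size = len(leaves[child])
        if size < min_cluster_size:
            return False
        gap = (parent_h - height[child]) / hmax
        return gap >= min_gap and scatter[child] / hmax <= max_scatter

    clusters: list[list[int]] = []

    def descend(node: int) -> None:
        if node < n:
            clusters.append(leaves[node])
            return
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        if distinct(a, height[node]) and distinct(b, height[node]):
            descend(a)
            descend(b)
        else:
            clusters.append(leaves[node])

    # top level: branches formed below the outlier height; leaves joining
    # above it are noise
    roots: list[int] = []

    def collect_roots(node: int) -> None:
        if node < n or height[node] <= outlier_height:
            roots.append(node)
            return
        collect_roots(int(Z[node - n, 0]))
        collect_roots(int(Z[node - n, 1]))

    collect_roots(2 * n - 2)
    for r in roots:
        descend(r)

    labels = pd.Series(0, index=genes, dtype=int)
    next_id = 1
    for members in clusters:
        if len(members) >= min_cluster_size:
            labels.iloc[members] = next_id
            next_id += 1
    cs = ClusterSet(labels=labels, params=params)
    if cs.n_clusters >= 2:
        sil, mss = silhouette_scores(labels, pd.DataFrame(D, index=genes, columns=genes))
        cs.silhouette = sil
        cs.mss = mss
    return cs


def silhouette_scores(
    labels: pd.Series, D: pd.DataFrame
) -> tuple[pd.Series, dict[int, float]]:
    """Per-gene silhouette on a precomputed dissimilarity plus per-cluster
    mean silhouette score (MSS); unassigned genes (label 0) are excluded."""
    assigned = labels.index[labels > 0]
    lab = labels.loc[assigned]
    if lab.nunique() < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    sub = D.loc[assigned, assigned].to_numpy(dtype=float)
    scores = silhouette_samples(sub, lab.to_numpy(), metric="precomputed")
    sil = pd.Series(scores, index=assigned, name="silhouette")
    mss = {int(k): float(sil[lab == k].mean()) for k in sorted(lab.unique())}
    return sil, mss
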