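"""Lineage-decoupled patient clustering.

The core procedure: (1) per-gene ordinary least squares of log2 expression
on FAB indicator variables (M2/M4/M5 against the M1 reference) flags genes
whose expression tracks lineage (BH q < 0.05 in any contrast); (2) flagged
genes are excluded and the residual high-variance genes (variance > 5 by
default) are kept; (3) samples are clustered by complete-linkage
hierarchical clustering on Euclidean distances and the dendrogram is cut
adaptively under a minimum-cluster-size constraint; (4) independence of the
resulting clusters from the binary lineage label (M1/M2 vs M4/M5) is tested
with the Fisher exact test.

The dendrogram cut places the cut level at the largest relative gap among
the top merge heights (bounded by n // min_cluster_size candidate levels):
every merge above the cut is severed, branches with at least
``min_cluster_size`` members become clusters, and smaller branches are
absorbed into the nearest cluster by average distance (or labelled 0 when
no cluster lies within the cut height).  On cleanly separated data this
coincides exactly with the static cut at the same number of branches, while
adapting the number of clusters to the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix, Scale
from .preprocess import variance_filter
from .stats import bh_adjust, fisher_exact_rxc

log = logging.getLogger(__name__)

__all__ = [
    "fit_fab_association",
    "exclude_and_select",
    "hierarchical_dendrogram",
    "dynamic_tree_cut",
    "lineage_association_test",
    "gene_count_sensitivity",
    "FabAssociationResult",
    "ClusterAssignment",
    "Dendrogram",
]

FAB_CONTRASTS = ("M2", "M4", "M5")


@dataclass
class FabAssociationResult:
    """Per-gene, per-contrast OLS coefficients with BH q-values.

    ``coefficients``/``p_values``/``q_values`` are gene x contrast frames
    (contrasts M2, M4, M5 vs the M1 reference; q computed within each
    contrast across genes); ``fab_associated`` flags genes significant in
    at least one contrast at ``q_threshold``.
    """

    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    q_values: pd.DataFrame
    fab_associated: pd.Series
    q_threshold: float


def fit_fab_association(
    log2_matrix: ExpressionMatrix,
    fab: pd.Series,
    q_threshold: float = 0.05,
) -> FabAssociationResult:
    """OLS screen of every gene's log2 expression on FAB indicators.

    Fits, per gene, expression ~ 1 + I(M2) + I(M4) + I(M5) with M1 as the
    reference level; each contrast's two-sided t p-values are BH-adjusted
    across genes, and a gene is flagged FAB-associated when any contrast
    has q below ``q_threshold``.
    """
    if log2_matrix.scale is not Scale.log2:
        raise ValueError("FAB association expects a log2 matrix")
    fab = fab.loc[log2_matrix.sample_ids]
    levels = fab.unique()
    if "M1" not in levels:
        raise ValueError("reference FAB level M1 is missing")
    counts = fab.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"FAB level(s) with < 2 samples: {list(small.index)}")
    present = [c for c in FAB_CONTRASTS if c in set(levels)]
    if not present:
        raise ValueError("need at least one non-reference FAB level")

    y = log2_matrix.data.to_numpy(dtype=float)  # genes x samples
    n = y.shape[1]
    x = np.column_stack(
        [np.ones(n)] + [(fab == c).to_numpy(dtype=float) for c in present]
    )
    k = x.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x k
    resid = y - beta @ x.T
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    t = np.where(se == 0, np.where(beta == 0, 0.0, np.sign(beta) * np.inf), t)
    p = 2 * sps.t.sf(np.abs(t), dof)
    p = np.where(np.isnan(p), 1.0, p)
    # constant genes: the regression is degenerate (statistic 0, p 1)
    flat = y.var(axis=1) < 1e-12
    t[flat], p[flat], beta[flat] = 0.0, 1.0, 0.0

    genes = log2_matrix.gene_ids
    coef = pd.DataFrame(beta[:, 1:], index=genes, columns=present)
    pvals = pd.DataFrame(p[:, 1:], index=genes, columns=present)
    qvals = pvals.apply(lambda col: bh_adjust(col.to_numpy()), axis=0)
    flagged = (qvals < q_threshold).any(axis=1)
    log.info("FAB-associated genes: %d / %d at q < %g", int(flagged.sum()),
             len(genes), q_threshold)
    return FabAssociationResult(coef, pvals, qvals, flagged, q_threshold)


def exclude_and_select(
    log2_matrix: ExpressionMatrix,
    fab_result: FabAssociationResult,
    variance_threshold: float = 5.0,
) -> list[str]:
    """Residual gene set: not FAB-associated AND sample variance above the
    threshold.  Empty result is an error advising a threshold change."""
    keep = set(fab_result.fab_associated.index[~fab_result.fab_associated])
    candidates = log2_matrix.subset_genes([g for g in log2_matrix.gene_ids
                                           if g in keep])
    selected = variance_filter(candidates, threshold=variance_threshold)
    if not selected:
        raise ValueError(
            "no gene survives FAB exclusion + variance filter; lower the "
            f"variance threshold (currently {variance_threshold})"
        )
    return selected


@dataclass
class Dendrogram:
    """Complete-linkage dendrogram over samples (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    distances: np.ndarray = field(repr=False)  # condensed Euclidean distances

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        from scipy.cluster.hierarchy import to_tree

        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def hierarchical_dendrogram(log2_matrix: ExpressionMatrix) -> Dendrogram:
    """Agglomerative clustering of samples: Euclidean distance between
    sample columns, complete linkage."""
    if log2_matrix.n_samples < 3:
        raise ValueError("need >= 3 samples to cluster")
    x = log2_matrix.data.to_numpy(dtype=float).T  # samples x genes
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression values")
    d = pdist(x, metric="euclidean")
    z = linkage(d, method="complete")
    return Dendrogram(z, log2_matrix.sample_ids, d)


@dataclass
class ClusterAssignment:
    """Sample -> cluster labels (1..K by decreasing size; 0 = unassigned)."""

    labels: pd.Series
    dendrogram: Dendrogram
    parameters: dict
    selected_genes: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int((pd.unique(self.labels[self.labels > 0])).size)

    def members(self, k: int) -> list[str]:
        return self.labels.index[self.labels == k].tolist()


def _components_after_cut(z: np.ndarray, n: int, cut: float) -> np.ndarray:
    """Connected components when merges above ``cut`` are severed."""
    parent = np.arange(2 * n - 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m, (a, b, h, _) in enumerate(z):
        node = n + m
        if h <= cut:
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def dynamic_tree_cut(
    dendrogram: Dendrogram,
    min_cluster_size: int = 8,
    cut_height_quantile: float = 0.99,
) -> ClusterAssignment:
    """Adaptive dendrogram cut with a minimum-cluster-size constraint.

    The cut level is chosen among the top ``n // min_cluster_size`` merge
    heights (never below the ``cut_height_quantile`` quantile of all merge
    heights) at the largest relative gap between consecutive sorted
    heights; all merges above it are severed.  Branches with at least
    ``min_cluster_size`` members become clusters (relabelled 1..K by
    decreasing size); smaller branches are absorbed into the nearest
    cluster by average Euclidean distance, or labelled 0 when that average
    exceeds the cut height.
    """
    n = len(dendrogram.sample_ids)
    if min_cluster_size > n:
        raise ValueError(f"min_cluster_size={min_cluster_size} exceeds n={n}")
    z = dendrogram.linkage_matrix
    heights = np.sort(dendrogram.merge_heights)[::-1]  # descending
    params = {
        "distance": "euclidean",
        "linkage": "complete",
        "min_cluster_size": min_cluster_size,
        "cut_height_quantile": cut_height_quantile,
    }

    if heights[0] <= 0:  # degenerate: all samples identical
        labels = pd.Series(1, index=dendrogram.sample_ids, name="cluster")
        return ClusterAssignment(labels, dendrogram, {**params, "cut_height": 0.0})

    # The static cut at the height quantile fixes the minimum number of
    # severed merges; the gap search may sever more, up to the largest
    # number of clusters the size constraint allows.
    qcut = float(np.quantile(dendrogram.merge_heights, cut_height_quantile))
    k_min = max(1, int((heights > qcut).sum()))
    k_max = max(k_min, min(n // min_cluster_size, len(heights) - 1))
    ks = range(k_min, k_max + 1)
    ratios = [np.inf if heights[k] == 0 else heights[k - 1] / heights[k] for k in ks]
    k_star = list(ks)[int(np.argmax(ratios))]
    cut = float((heights[k_star - 1] + heights[k_star]) / 2)

    comp = _components_after_cut(z, n, cut)
    sizes = np.bincount(comp)
    viable = np.flatnonzero(sizes >= min_cluster_size)
    dmat = squareform(dendrogram.distances)
    labels = np.zeros(n, dtype=int)

    if viable.size == 0:
        # no branch reaches the minimum size: keep everything together
        labels[:] = 1
        log.warning("no branch reaches min_cluster_size=%d; single cluster",
                    min_cluster_size)
    else:
        # order viable clusters by decreasing size (stable on ties)
        order = viable[np.argsort(-sizes[viable], kind="stable")]
        for rank, c in enumerate(order, start=1):
            labels[comp == c] = rank
        for c in np.flatnonzero(sizes < min_cluster_size):
            members = np.flatnonzero(comp == c)
            avg = np.array(
                [dmat[np.ix_(members, np.flatnonzero(labels == r))].mean()
                 for r in range(1, len(order) + 1)]
            )
            best = int(np.argmin(avg))
            if avg[best] <= cut:
                labels[members] = best + 1
            # else remain 0 (unassigned)

    series = pd.Series(labels, index=dendrogram.sample_ids, name="cluster")
    return ClusterAssignment(series, dendrogram, {**params, "cut_height": cut})


def lineage_association_test(assignment: ClusterAssignment, lineage: pd.Series) -> float:
    """Fisher exact p for the K x 2 cluster-by-lineage table (M1/M2 vs
    M4/M5); unassigned samples (label 0) are excluded."""
    labels = assignment.labels[assignment.labels > 0]
    lineage = lineage.loc[labels.index]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters for the lineage test")
    lin_levels = sorted(lineage.dropna().unique())
    table = np.array(
        [[int(((labels == k) & (lineage == l)).sum()) for l in lin_levels]
         for k in clusters]
    )
    try:
        return fisher_exact_rxc(table)
    except ValueError:
        return fisher_exact_rxc(table, monte_carlo=True, seed=0)


def gene_count_sensitivity(
    log2_matrix: ExpressionMatrix,
    lineage: pd.Series,
    counts: tuple[int, ...] = (1000, 1500, 2000, 2500, 3000),
    min_cluster_size: int = 8,
) -> pd.DataFrame:
    """Sweep of naive (no FAB exclusion) clustering over top-variance gene
    counts: for each count, cluster on the top-N variance genes and test
    lineage association.  Returns a table (n_genes, n_clusters, fisher_p)."""
    rows = []
    for count in counts:
        genes = variance_filter(log2_matrix, top_n=count)
        assignment = dynamic_tree_cut(
            hierarchical_dendrogram(log2_matrix.subset_genes(genes)),
            min_cluster_size=min_cluster_size,
        )
        p = lineage_association_test(assignment, lineage)
        rows.append({"n_genes": count, "n_clusters": assignment.n_clusters,
                     "fisher_p": p})
    return pd.DataFrame(rows)
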