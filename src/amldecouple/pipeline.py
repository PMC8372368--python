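"""End-to-end workflow helpers tying the stages together.

These are the compositions the command-line interface and the worked
examples run: counts -> median-of-ratios + log2 -> FAB-association screen
-> exclusion + variance selection -> dendrogram + adaptive cut -> lineage
independence test, and the naive (no exclusion) top-variance counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cluster import (
    ClusterAssignment,
    FabAssociationResult,
    dynamic_tree_cut,
    exclude_and_select,
    fit_fab_association,
    hierarchical_dendrogram,
    lineage_association_test,
)
from .containers import ClinicalTable, ExpressionMatrix, Scale
from .preprocess import log2_transform, normalize_median_of_ratios, variance_filter

__all__ = ["preprocess_counts", "decoupled_clustering", "naive_clustering",
           "DecoupledClusteringResult"]


def preprocess_counts(counts: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Median-of-ratios normalization followed by log2(x + pseudocount)."""
    normalized, _ = normalize_median_of_ratios(counts)
    return log2_transform(normalized, pseudocount)


@dataclass
class DecoupledClusteringResult:
    fab_association: FabAssociationResult
    selected_genes: list[str]
    assignment: ClusterAssignment
    lineage_fisher_p: float


def decoupled_clustering(
    log2_matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    variance_threshold: float = 5.0,
    fab_q_threshold: float = 0.05,
    min_cluster_size: int = 8,
) -> DecoupledClusteringResult:
    """The lineage-decoupled clustering workflow on a log2 matrix."""
    if log2_matrix.scale is not Scale.log2:
        raise ValueError("expected a log2 matrix (see preprocess_counts)")
    fab = clinical.data.loc[log2_matrix.sample_ids, "fab"]
    fab_result = fit_fab_association(log2_matrix, fab, q_threshold=fab_q_threshold)
    selected = exclude_and_select(log2_matrix, fab_result,
                                  variance_threshold=variance_threshold)
    dendrogram = hierarchical_dendrogram(log2_matrix.subset_genes(selected))
    assignment = dynamic_tree_cut(dendrogram, min_cluster_size=min_cluster_size)
    assignment.selected_genes = selected
    lineage = clinical.lineage().loc[log2_matrix.sample_ids]
    p = lineage_association_test(assignment, lineage)
    return DecoupledClusteringResult(fab_result, selected, assignment, p)


def naive_clustering(
    log2_matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    top_n: int = 1000,
    min_cluster_size: int = 8,
) -> tuple[ClusterAssignment, float]:
    """Top-variance clustering without FAB exclusion, plus the lineage
    association Fisher p."""
    genes = variance_filter(log2_matrix, top_n=top_n)
    assignment = dynamic_tree_cut(
        hierarchical_dendrogram(log2_matrix.subset_genes(genes)),
        min_cluster_size=min_cluster_size,
    )
    assignment.selected_genes = genes
    lineage = clinical.lineage().loc[log2_matrix.sample_ids]
    return assignment, lineage_association_test(assignment, lineage)
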