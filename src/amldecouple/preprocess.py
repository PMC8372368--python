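"""Normalization, log2 transform, variance filtering, two-group differential
expression, and up/down signature extraction.

Counts are normalized with the median-of-ratios size-factor method: each
sample's size factor is the median, over genes whose geometric mean across
samples is positive, of that sample's count divided by the gene's geometric
mean.  Differential expression is a per-gene Welch two-sample t-test on
log2-normalized values with BH correction — the downstream consumers only
need a signed per-gene statistic, a log2 fold change and an FDR q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, Scale
from .stats import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "normalize_median_of_ratios",
    "log2_transform",
    "variance_filter",
    "differential_expression",
    "select_signature_genes",
    "DEResult",
    "SignatureGeneSets",
]


def normalize_median_of_ratios(
    counts: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios normalization of a raw count matrix.

    Returns the normalized matrix and the per-sample size factors
    s_j = median over reference genes g of count_gj / geomean_g, where the
    reference genes are those with a positive geometric mean (i.e. nonzero
    in every sample).  Size factors are rescaled to geometric mean 1 — a
    pure rescaling of the whole matrix that makes normalization idempotent.
    """
    if counts.scale is not Scale.raw_counts:
        raise ValueError("normalization expects raw counts")
    mat = counts.data.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        j = int(np.flatnonzero(mat.sum(axis=0) == 0)[0])
        raise ValueError(f"sample {counts.sample_ids[j]!r} has all-zero counts")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "needs an all-positive reference set (consider a pseudo-reference "
            "fallback upstream)"
        )
    log_geomean = np.log(mat[positive]).mean(axis=1)
    ratios = np.log(mat[positive]) - log_geomean[:, None]
    log_sf = np.median(ratios, axis=0)
    size_factors = np.exp(log_sf - log_sf.mean())
    normalized = ExpressionMatrix(
        pd.DataFrame(mat / size_factors, index=counts.data.index,
                     columns=counts.data.columns),
        Scale.normalized_counts,
    )
    return normalized, pd.Series(size_factors, index=counts.sample_ids, name="size_factor")


def log2_transform(normalized: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) of a normalized matrix."""
    if normalized.scale is Scale.log2:
        raise ValueError("matrix is already on the log2 scale")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = normalized.data.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative values cannot be log2-transformed")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(vals + pseudocount), index=normalized.data.index,
                     columns=normalized.data.columns),
        Scale.log2,
    )


def variance_filter(
    log2_matrix: ExpressionMatrix,
    threshold: float | None = None,
    top_n: int | None = None,
) -> list[str]:
    """Genes passing a sample-variance filter on the log2 matrix.

    Exactly one of ``threshold`` (keep variance > threshold) or ``top_n``
    (keep the n highest-variance genes) must be given; variance uses the
    n-1 denominator.
    """
    if log2_matrix.scale is not Scale.log2:
        raise ValueError("variance filter expects a log2 matrix")
    if (threshold is None) == (top_n is None):
        raise ValueError("specify exactly one of threshold or top_n")
    var = log2_matrix.data.var(axis=1, ddof=1)
    if threshold is not None:
        return var.index[var > threshold].tolist()
    if top_n > len(var):
        raise ValueError(f"top_n={top_n} exceeds the {len(var)} genes available")
    return var.sort_values(ascending=False, kind="stable").index[:top_n].tolist()


@dataclass
class DEResult:
    """Per-gene two-group differential expression table.

    Columns: log2_fold_change (A minus B on the log2 scale), statistic
    (Welch t), p, q (BH), mean_a, mean_b.
    """

    table: pd.DataFrame
    group_a: list[str]
    group_b: list[str]


def differential_expression(
    log2_matrix: ExpressionMatrix,
    samples_a: list[str],
    samples_b: list[str],
) -> DEResult:
    """Welch t differential expression of group A over group B on log2 values.

    Genes with zero variance in both groups get statistic 0 and p 1.
    """
    if set(samples_a) & set(samples_b):
        raise ValueError("groups overlap")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 samples per group")
    if log2_matrix.scale is not Scale.log2:
        raise ValueError("differential expression expects a log2 matrix")
    a = log2_matrix.data[list(samples_a)].to_numpy(dtype=float)
    b = log2_matrix.data[list(samples_b)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    flat = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    stat = np.where(flat & (mean_a == mean_b), 0.0, stat)
    p = np.where(flat & (mean_a == mean_b), 1.0, p)
    # constant-but-different genes: infinite separation
    hard = flat & (mean_a != mean_b)
    stat = np.where(hard, np.sign(mean_a - mean_b) * np.inf, stat)
    p = np.where(hard, 0.0, p)
    table = pd.DataFrame(
        {
            "log2_fold_change": mean_a - mean_b,
            "statistic": stat,
            "p": p,
            "q": bh_adjust(p),
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=log2_matrix.data.index,
    )
    return DEResult(table, list(samples_a), list(samples_b))


@dataclass
class SignatureGeneSets:
    """Up/down signature gene lists with the thresholds that produced them."""

    up: list[str]
    down: list[str]
    lfc_cut: float
    q_cut: float


def select_signature_genes(
    de: DEResult, lfc_cut: float = 2.0, q_cut: float = 0.05
) -> SignatureGeneSets:
    """Signature genes: up = log2FC > lfc_cut and q < q_cut; down = log2FC
    < -lfc_cut and q < q_cut.  Empty sets are allowed (logged)."""
    t = de.table
    up = t.index[(t["log2_fold_change"] > lfc_cut) & (t["q"] < q_cut)].tolist()
    down = t.index[(t["log2_fold_change"] < -lfc_cut) & (t["q"] < q_cut)].tolist()
    if not up or not down:
        log.warning("signature selection: %d up, %d down genes", len(up), len(down))
    return SignatureGeneSets(up, down, lfc_cut, q_cut)
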