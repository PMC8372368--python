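"""Gene-set enrichment: parametric set tests on per-gene statistics,
single-sample GSEA (ssGSEA) activity scores, group comparisons of pathway
activity, and score-based stratification.

ssGSEA scores depend only on within-sample expression ranks: genes are
ordered by decreasing expression; the score is the sum over rank positions
of the difference between the weighted empirical CDF of the set's member
genes (weights = rank^alpha, alpha = 0.25 by default) and the unweighted
empirical CDF of the non-members.  The set-level test compares member
against non-member per-gene statistics with a Welch t-test ("mean
T-statistic" summaries), BH-corrected across sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, GeneSetCollection, Scale
from .stats import bh_adjust, wilcoxon_rank_sum

log = logging.getLogger(__name__)

__all__ = [
    "gsea_set_test",
    "ssgsea_score",
    "compare_pathway_activity",
    "group_likeness_score",
    "score_stratify_median",
    "PathwayScoreMatrix",
    "LikenessScore",
]


def gsea_set_test(
    statistics: pd.Series,
    collection: GeneSetCollection,
    q_cut: float = 0.1,
) -> pd.DataFrame:
    """Set-level enrichment of per-gene statistics (e.g. DE t-statistics).

    Per set: Welch two-sample t of member vs non-member statistics
    (two-sided), the mean member statistic, direction (sign of member mean
    minus background mean), and BH q across tested sets; ``significant``
    marks q < ``q_cut``.  Sets with fewer than 2 member genes present are
    skipped with a warning.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    stats_vec = statistics.dropna()
    genes = set(stats_vec.index)
    rows = []
    for name, members in collection.sets.items():
        inside = [g for g in members if g in genes]
        if len(inside) < 2:
            warnings.warn(f"set {name!r}: fewer than 2 member genes present; skipped")
            continue
        member_stats = stats_vec.loc[inside].to_numpy()
        outside = stats_vec.drop(index=inside).to_numpy()
        t, p = sps.ttest_ind(member_stats, outside, equal_var=False)
        mean_member = float(member_stats.mean())
        rows.append(
            {
                "set": name,
                "n_genes": len(inside),
                "mean_statistic": mean_member,
                "direction": "up" if mean_member >= outside.mean() else "down",
                "t": float(t),
                "p": float(p),
            }
        )
    if not rows:
        raise ValueError("no testable set (all below 2 member genes)")
    result = pd.DataFrame(rows).set_index("set")
    result["q"] = bh_adjust(result["p"])
    result["significant"] = result["q"] < q_cut
    return result


@dataclass
class PathwayScoreMatrix:
    """Gene-set x sample ssGSEA activity scores."""

    scores: pd.DataFrame
    alpha: float
    normalized: bool = False


def _ssgsea_sample(order: np.ndarray, ranks: np.ndarray, member_mask: np.ndarray,
                   alpha: float) -> float:
    # order: gene indices by decreasing expression; ranks: 1..n with n = top
    in_set = member_mask[order]
    weights = ranks[order] ** alpha
    w_in = np.where(in_set, weights, 0.0)
    denom_in = w_in.sum()
    cdf_in = np.cumsum(w_in) / denom_in
    n_out = (~member_mask).sum()
    cdf_out = np.cumsum(~in_set) / n_out
    return float((cdf_in - cdf_out).sum())


def ssgsea_score(
    log2_matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> PathwayScoreMatrix:
    """Single-sample GSEA activity scores for every set and sample.

    Ties in expression are broken by the stable gene order of the matrix.
    Each set must leave a non-empty complement in the gene universe.  With
    ``normalize=True`` scores are min-max rescaled across samples (off by
    default; downstream median splits are normalization-invariant).
    """
    if log2_matrix.scale is Scale.raw_counts:
        raise ValueError("ssGSEA expects normalized or log2 expression")
    data = log2_matrix.data
    n = data.shape[0]
    universe = {g: i for i, g in enumerate(data.index)}
    masks = {}
    for name, members in collection.sets.items():
        idx = [universe[g] for g in members if g in universe]
        if not idx:
            warnings.warn(f"set {name!r}: no member genes in the matrix; skipped")
            continue
        if len(idx) == n:
            raise ValueError(f"set {name!r} covers every gene; complement is empty")
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        masks[name] = mask
    if not masks:
        raise ValueError("no scorable gene set")

    values = data.to_numpy(dtype=float)
    scores = np.zeros((len(masks), data.shape[1]))
    # ranks: highest expression gets rank n; stable order for ties
    for j in range(values.shape[1]):
        order = np.argsort(-values[:, j], kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(n, 0, -1)
        for i, mask in enumerate(masks.values()):
            scores[i, j] = _ssgsea_sample(order, ranks, mask, alpha)
    frame = pd.DataFrame(scores, index=list(masks), columns=data.columns)
    if normalize:
        rng = frame.max(axis=1) - frame.min(axis=1)
        frame = frame.sub(frame.min(axis=1), axis=0).div(rng.replace(0, 1), axis=0)
    return PathwayScoreMatrix(frame, alpha, normalize)


def compare_pathway_activity(
    score_matrix: PathwayScoreMatrix,
    group_a: list[str],
    group_b: list[str],
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-set Wilcoxon rank-sum comparison of activity between two groups,
    BH across sets; direction from the median difference (A vs B)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    a = score_matrix.scores[list(group_a)]
    b = score_matrix.scores[list(group_b)]
    rows = []
    for name in score_matrix.scores.index:
        stat, p = wilcoxon_rank_sum(a.loc[name], b.loc[name])
        delta = float(a.loc[name].median() - b.loc[name].median())
        rows.append({"set": name, "median_diff": delta,
                     "direction": "up" if delta >= 0 else "down", "p": p})
    result = pd.DataFrame(rows).set_index("set")
    result["q"] = bh_adjust(result["p"])
    result["significant"] = result["q"] < q_cut
    return result


@dataclass
class LikenessScore:
    """Per-sample signature score: ssGSEA(up) - ssGSEA(down), median-split."""

    table: pd.DataFrame  # up_activity, down_activity, score, stratum
    alpha: float

    @property
    def strata(self) -> pd.Series:
        return self.table["stratum"]


def group_likeness_score(
    log2_matrix: ExpressionMatrix,
    up: list[str],
    down: list[str],
    alpha: float = 0.25,
) -> LikenessScore:
    """Score each sample by the difference between the ssGSEA activity of
    the up- and down-signature gene sets, then median-split into high/low
    strata (ties and the odd-n midpoint go high)."""
    present = set(log2_matrix.gene_ids)
    lost_up = [g for g in up if g not in present]
    lost_down = [g for g in down if g not in present]
    if len(lost_up) == len(up) or len(lost_down) == len(down):
        raise ValueError(
            "signature set empty after intersection with the matrix; lost "
            f"up genes {lost_up[:5]}..., down genes {lost_down[:5]}..."
        )
    collection = GeneSetCollection({"up": [g for g in up if g in present],
                                    "down": [g for g in down if g in present]})
    scores = ssgsea_score(log2_matrix, collection, alpha=alpha).scores
    score = scores.loc["up"] - scores.loc["down"]
    strata = score_stratify_median(score)
    table = pd.DataFrame(
        {"up_activity": scores.loc["up"], "down_activity": scores.loc["down"],
         "score": score, "stratum": strata}
    )
    return LikenessScore(table, alpha)


def score_stratify_median(scores: pd.Series) -> pd.Series:
    """Median split of a score vector into 'high' (score >= median, so ties
    and the odd-n middle sample go high) and 'low' strata."""
    scores = pd.Series(scores).astype(float)
    if scores.size < 4:
        raise ValueError("need >= 4 samples for a median split")
    if scores.nunique() == 1:
        raise ValueError("all scores identical: no median split possible")
    median = scores.median()
    return pd.Series(np.where(scores >= median, "high", "low"),
                     index=scores.index, name="stratum")
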