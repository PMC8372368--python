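"""Shared statistical kernel: contingency tests, FDR, rank tests,
correlations, and the mutation / protein (RPPA) association analyses.

The Fisher exact test for r x c tables is implemented by full enumeration
of all tables with the observed margins (the point-probability two-sided
rule: the p-value sums the probability of every table whose conditional
hypergeometric probability does not exceed that of the observed table).
No installed Python package provides the r x c exact test, so this is the
one kernel primitive written from scratch; a seeded Monte Carlo fallback
covers tables too large to enumerate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import MutationMatrix, ProteinMatrix

__all__ = [
    "chi_square_test",
    "fisher_exact_rxc",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "spearman_correlation",
    "kruskal_wallis",
    "group_comparison_test",
    "mutation_analysis",
    "rppa_differential",
    "MutationAssociationResult",
    "ProteinDifferential",
]

# Enumeration guard: beyond this the exact test errors and suggests the
# Monte Carlo fallback.
_MAX_TOTAL = 200
_MAX_DIM = 4


def _validate_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("contingency table must hold integer counts")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero margin")
    return t.astype(np.int64)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns (statistic, df, p).  Warns when any expected count is below 5,
    the usual trigger for preferring the exact test.
    """
    t = _validate_table(table)
    stat, p, df, expected = sps.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        warnings.warn(
            "chi-square expected count < 5; consider fisher_exact_rxc",
            stacklevel=2,
        )
    return float(stat), int(df), float(p)


def _log_table_prob(table: np.ndarray, lf: np.ndarray) -> float:
    # log hypergeometric probability of a table given its margins
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (
        lf[rows].sum() + lf[cols].sum() - lf[n] - lf[table].sum()
    )


def fisher_exact_rxc(
    table,
    monte_carlo: bool = False,
    n_replicates: int = 100_000,
    seed: int | None = None,
) -> float:
    """Two-sided Fisher exact test for an r x c table.

    Enumerates every table with the observed margins; p is the total
    conditional probability of tables no more probable than the observed
    one (with the customary 1e-7 relative tolerance).  Tables larger than
    4 x 4 or with total count > 200 require ``monte_carlo=True``, which
    draws seeded random tables with the observed margins by permutation.
    """
    t = _validate_table(table)
    n = int(t.sum())
    r, c = t.shape
    if c < r:  # enumerate over the smaller dimension's rows
        t = t.T
        r, c = c, r
    lf = np.array([math.lgamma(k + 1) for k in range(n + 1)])
    log_obs = _log_table_prob(t, lf)
    threshold = log_obs + 1e-7

    if monte_carlo or r > _MAX_DIM or c > _MAX_DIM or n > _MAX_TOTAL:
        if not monte_carlo:
            raise ValueError(
                f"table too large for exact enumeration ({r}x{c}, n={n}); "
                "pass monte_carlo=True"
            )
        rng = np.random.default_rng(seed)
        rows = np.repeat(np.arange(r), t.sum(axis=1))
        cols = np.repeat(np.arange(c), t.sum(axis=0))
        hits = 0
        for _ in range(n_replicates):
            perm = rng.permutation(cols)
            sim = np.zeros((r, c), dtype=np.int64)
            np.add.at(sim, (rows, perm), 1)
            if _log_table_prob(sim, lf) <= threshold:
                hits += 1
        return (hits + 1) / (n_replicates + 1)

    row_margins = t.sum(axis=1)
    col_margins = t.sum(axis=0)
    # order rows by margin ascending: small rows first prunes the search
    order = np.argsort(row_margins, kind="stable")
    row_margins = row_margins[order]

    # constant part of every table's log probability
    const = lf[row_margins].sum() + lf[col_margins].sum() - lf[n]
    p_total = 0.0

    def recurse(i: int, remaining: np.ndarray, log_acc: float) -> None:
        nonlocal p_total
        if i == r - 1:
            lp = const + log_acc - lf[remaining].sum()
            if lp <= threshold:
                p_total += math.exp(lp)
            return
        target = int(row_margins[i])
        row = np.zeros(c, dtype=np.int64)

        def fill(j: int, left: int, log_row: float) -> None:
            if j == c - 1:
                if left > remaining[j]:
                    return
                row[j] = left
                recurse(i + 1, remaining - row, log_acc + log_row - lf[left])
                row[j] = 0
                return
            hi = min(left, int(remaining[j]))
            lo = max(0, left - int(remaining[j + 1:].sum()))
            for k in range(lo, hi + 1):
                row[j] = k
                fill(j + 1, left - k, log_row - lf[k])
            row[j] = 0

        fill(0, target, 0.0)

    recurse(0, col_margins.copy(), 0.0)
    return min(1.0, p_total)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), in the
    input order, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution when the smaller sample has <= 10 observations
    and there are no ties; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (tie-aware mid-ranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups (continuous Table-1 rows)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def group_comparison_test(table, seed: int | None = None) -> tuple[str, float]:
    """Categorical group-comparison test with the expected-count rule:
    Fisher exact if any expected count < 5, else Pearson chi-square.

    Returns (test name, p).  This is the rule behind mixed-test clinical
    characteristics tables.
    """
    t = _validate_table(table)
    expected = sps.chi2_contingency(t, correction=False)[3]
    if (expected < 5).any():
        try:
            return "fisher", fisher_exact_rxc(t)
        except ValueError:
            return "fisher_mc", fisher_exact_rxc(t, monte_carlo=True, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, p = chi_square_test(t)
    return "chi_square", p


# ---------------------------------------------------------------------------
# Mutation and protein analyses


@dataclass
class MutationAssociationResult:
    """Per-gene cluster association and per-pair co-occurrence tests."""

    cluster_association: pd.DataFrame  # gene, frequency, p, q + count columns
    cooccurrence: pd.DataFrame  # gene_a, gene_b, odds_ratio, p, q, zero_cell_corrected
    frequency_threshold: float


def mutation_analysis(
    mutations: MutationMatrix,
    clusters: pd.Series,
    frequency_threshold: float = 0.10,
    seed: int | None = None,
    pairwise: bool = True,
) -> MutationAssociationResult:
    """Mutation-cluster association and pairwise co-occurrence.

    Genes mutated in fewer than ``frequency_threshold`` of samples are
    excluded.  Each remaining gene is tested with the Fisher exact test on
    its mutated/wild-type x cluster table (BH-adjusted across genes), and
    every gene pair with a 2 x 2 Fisher test plus odds ratio (OR > 1
    co-occurrence, OR < 1 mutual exclusivity; Haldane 0.5 correction only
    when a cell is zero, flagged in the output).  ``pairwise=False`` skips
    the co-occurrence scan.
    """
    clusters = clusters.dropna()
    clusters = clusters[clusters != 0]
    if clusters.nunique() < 2:
        raise ValueError("need >= 2 clusters")
    shared = [s for s in mutations.sample_ids if s in set(clusters.index)]
    calls = mutations.data[shared]
    labels = clusters.loc[shared]
    freq = calls.mean(axis=1)
    tested = freq[freq >= frequency_threshold].index.tolist()
    if not tested:
        warnings.warn("no gene passes the mutation frequency filter")
        empty = pd.DataFrame()
        return MutationAssociationResult(empty, empty, frequency_threshold)

    cluster_levels = sorted(labels.unique())
    rows = []
    for gene in tested:
        mut = calls.loc[gene]
        table = np.array(
            [
                [int(((mut == 1) & (labels == k)).sum()) for k in cluster_levels],
                [int(((mut == 0) & (labels == k)).sum()) for k in cluster_levels],
            ]
        )
        try:
            p = fisher_exact_rxc(table, seed=seed)
        except ValueError:
            p = fisher_exact_rxc(table, monte_carlo=True, seed=seed)
        enriched = cluster_levels[int(np.argmax(table[0] / table.sum(axis=0)))]
        rows.append({"gene": gene, "frequency": float(freq[gene]),
                     "enriched_cluster": enriched, "p": p})
    assoc = pd.DataFrame(rows).set_index("gene")
    assoc["q"] = bh_adjust(assoc["p"])

    pair_rows = []
    for a, b in combinations(tested if pairwise else [], 2):
        ma, mb = calls.loc[a], calls.loc[b]
        t11 = int(((ma == 1) & (mb == 1)).sum())
        t10 = int(((ma == 1) & (mb == 0)).sum())
        t01 = int(((ma == 0) & (mb == 1)).sum())
        t00 = int(((ma == 0) & (mb == 0)).sum())
        table = np.array([[t11, t10], [t01, t00]])
        zero = (table == 0).any()
        ct = table + 0.5 if zero else table
        odds = (ct[0, 0] * ct[1, 1]) / (ct[0, 1] * ct[1, 0])
        p = fisher_exact_rxc(table) if table.sum() <= _MAX_TOTAL else \
            float(sps.fisher_exact(table)[1])
        pair_rows.append({"gene_a": a, "gene_b": b, "odds_ratio": float(odds),
                          "p": p, "zero_cell_corrected": bool(zero)})
    cooc = pd.DataFrame(pair_rows)
    if len(cooc):
        cooc["q"] = bh_adjust(cooc["p"])
    return MutationAssociationResult(assoc, cooc, frequency_threshold)


@dataclass
class ProteinDifferential:
    """Per-protein two-group differential result with percentile selection."""

    table: pd.DataFrame  # protein, mean_diff, p, q, selected_up, selected_down
    up_threshold: float
    down_threshold: float
    q_cut: float


def rppa_differential(
    proteins: ProteinMatrix,
    group_a: list[str],
    group_b: list[str],
    q_cut: float = 0.1,
) -> ProteinDifferential:
    """Differential protein expression between two sample groups.

    Per protein: difference in means (A minus B) with a Wilcoxon rank-sum p
    and BH q.  Selected up/down = difference beyond the 75th/25th percentile
    of all per-protein differences AND q below ``q_cut``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    a = proteins.data[list(group_a)].to_numpy(dtype=float)
    b = proteins.data[list(group_b)].to_numpy(dtype=float)
    diffs = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.array([wilcoxon_rank_sum(a[i], b[i])[1] for i in range(a.shape[0])])
    q = bh_adjust(pvals)
    hi = float(np.percentile(diffs, 75))
    lo = float(np.percentile(diffs, 25))
    table = pd.DataFrame(
        {
            "mean_diff": diffs,
            "p": pvals,
            "q": q,
            "selected_up": (diffs > hi) & (q < q_cut),
            "selected_down": (diffs < lo) & (q < q_cut),
        },
        index=proteins.data.index,
    )
    return ProteinDifferential(table, hi, lo, q_cut)
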