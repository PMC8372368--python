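"""Statistical kernel: exact tests, FDR, rank tests, mutation/protein analyses.

The Fisher r x c test is checked against an independent brute-force
enumeration written here (which also verifies that the conditional
probabilities over all tables with the observed margins sum to 1), against
scipy's two-sided 2 x 2 test, and against printed clinical-table values.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from amldecouple.containers import MutationMatrix, ProteinMatrix
from amldecouple.stats import (
    bh_adjust,
    chi_square_test,
    fisher_exact_rxc,
    group_comparison_test,
    kruskal_wallis,
    mutation_analysis,
    rppa_differential,
    spearman_correlation,
    wilcoxon_rank_sum,
)


def enumerate_tables(row_margins, col_margins):
    """Brute-force generator of all tables with the given margins."""
    r, c = len(row_margins), len(col_margins)

    def rows_for(total):
        for combo in itertools.product(*(range(m + 1) for m in col_margins)):
            if sum(combo) == total:
                yield combo

    def recurse(i, cols_left, acc):
        if i == r:
            if all(x == 0 for x in cols_left):
                yield np.array(acc)
            return
        for row in rows_for(row_margins[i]):
            if all(row[j] <= cols_left[j] for j in range(c)):
                yield from recurse(
                    i + 1, [cols_left[j] - row[j] for j in range(c)], acc + [row]
                )

    yield from recurse(0, list(col_margins), [])


def table_prob(table):
    t = np.asarray(table)
    n = t.sum()
    lf = math.lgamma
    logp = (
        sum(lf(x + 1) for x in t.sum(axis=1))
        + sum(lf(x + 1) for x in t.sum(axis=0))
        - lf(n + 1)
        - sum(lf(x + 1) for x in t.ravel())
    )
    return math.exp(logp)


def brute_force_fisher(table):
    t = np.asarray(table)
    obs = table_prob(t)
    p = 0.0
    for cand in enumerate_tables(t.sum(axis=1), t.sum(axis=0)):
        prob = table_prob(cand)
        if prob <= obs * (1 + 1e-7):
            p += prob
    return p


class TestFisherExact:
    def test_2x2_hypergeometric_enumeration(self):
        assert fisher_exact_rxc([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-12)

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.integers(0, 15, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            expected = sps.fisher_exact(t)[1]
            assert fisher_exact_rxc(t) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize(
        "table",
        [[[2, 3, 1], [4, 0, 2]], [[1, 2], [3, 4], [5, 0]], [[3, 1], [1, 3]]],
    )
    def test_matches_brute_force_enumeration(self, table):
        assert fisher_exact_rxc(table) == pytest.approx(
            brute_force_fisher(table), rel=1e-9
        )

    @pytest.mark.parametrize(
        "row_margins,col_margins",
        [((4, 4), (4, 4)), ((3, 5, 2), (4, 4, 2)), ((6, 3), (2, 3, 4))],
    )
    def test_conditional_probabilities_sum_to_one(self, row_margins, col_margins):
        total = sum(
            table_prob(t) for t in enumerate_tables(row_margins, col_margins)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_monte_carlo_approximates_exact(self):
        table = [[8, 2], [3, 9]]
        exact = fisher_exact_rxc(table)
        mc = fisher_exact_rxc(table, monte_carlo=True, n_replicates=50_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_large_table_requires_monte_carlo(self):
        big = np.full((5, 5), 20)
        with pytest.raises(ValueError, match="monte_carlo"):
            fisher_exact_rxc(big)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_rxc([[0, 0], [1, 2]])


class TestChiSquare:
    def test_balanced_table_is_null(self):
        stat, df, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_recent_ahd_clinical_table(self):
        # 2x3 antecedent-hematologic-disorder by group counts
        _, _, p = chi_square_test([[16, 16, 16], [15, 13, 5]])
        assert p == pytest.approx(0.180, abs=0.006)

    def test_2x2_closed_form(self):
        a, b, c, d = 7, 3, 2, 9
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, df, _ = chi_square_test([[a, b], [c, d]])
        assert stat == pytest.approx(expected, rel=1e-12) and df == 1

    def test_row_column_permutation_invariance(self):
        t = np.array([[5, 1, 4], [2, 8, 3]])
        base = chi_square_test(t)[0]
        assert chi_square_test(t[::-1])[0] == pytest.approx(base)
        assert chi_square_test(t[:, [2, 0, 1]])[0] == pytest.approx(base)


class TestGroupComparison:
    def test_low_expected_counts_use_fisher(self):
        test, p = group_comparison_test([[2, 8, 1], [29, 21, 20]])
        assert test == "fisher"
        assert p == pytest.approx(0.028, abs=0.0015)

    def test_adequate_counts_use_chi_square(self):
        test, _ = group_comparison_test([[12, 10, 12], [19, 19, 9]])
        assert test == "chi_square"


class TestBhAdjust:
    def test_hand_step_up(self):
        q = bh_adjust([0.002, 0.01, 0.03, 0.04])
        assert q == pytest.approx([0.008, 0.02, 0.04, 0.04])

    def test_all_equal_and_singleton(self):
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])
        assert bh_adjust([0.07]) == pytest.approx([0.07])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_never_decreases_and_step_up_monotone_property(self, pvals):
        q = bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        # adjusted values sorted by p are non-decreasing (step-up shape)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRankStats:
    def test_wilcoxon_exact_small_sample(self):
        # complete separation of 3 vs 3: 2 of 20 arrangements are as extreme
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_wilcoxon_translation_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=25)
        assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(
            wilcoxon_rank_sum(x + 100, y + 100)[1]
        )

    def test_wilcoxon_rejects_empty(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_spearman_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_correlation(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_spearman_with_ties_matches_rank_pearson(self):
        x = np.array([1.0, 2, 2, 3, 5, 5, 5, 8])
        y = np.array([3.0, 1, 4, 4, 6, 2, 7, 9])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlation(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_spearman_rejects_constant(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_kruskal_wallis_runs(self):
        stat, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert p < 0.05 or stat > 0


class TestMutationAnalysis:
    @staticmethod
    def _matrix(calls: dict, samples):
        return MutationMatrix(pd.DataFrame(calls, index=samples).T)

    def test_low_frequency_gene_excluded(self, cohort):
        rng = np.random.default_rng(3)
        n = 81
        samples = [f"S{i}" for i in range(n)]
        rare = np.zeros(n, dtype=int)
        rare[:5] = 1  # 5/81 ~ 6% < 10%
        common = rng.integers(0, 2, n)
        mut = self._matrix({"RARE": rare, "COMMON": common}, samples)
        clusters = pd.Series(rng.choice([1, 2, 3], n), index=samples)
        result = mutation_analysis(mut, clusters)
        assert "RARE" not in result.cluster_association.index
        assert "COMMON" in result.cluster_association.index

    def test_odds_ratio_cross_product(self):
        # arrange co-mutation pattern with 2x2 table [[10,2],[3,9]]
        a = [1] * 12 + [0] * 12
        b = [1] * 10 + [0] * 2 + [1] * 3 + [0] * 9
        samples = [f"S{i}" for i in range(24)]
        mut = self._matrix({"GENEA": a, "GENEB": b}, samples)
        clusters = pd.Series([1, 2] * 12, index=samples)
        result = mutation_analysis(mut, clusters)
        row = result.cooccurrence.iloc[0]
        assert row["odds_ratio"] == pytest.approx(15.0)
        assert not row["zero_cell_corrected"]

    def test_planted_drivers_recovered(self, cohort):
        """Per-driver power at n = 81 is below 1, so a single cohort is
        required to recover most drivers (all of them are checked with
        proper replication in the acceptance suite)."""
        result = mutation_analysis(cohort.mutations, cohort.latent_groups, seed=0)
        assoc = result.cluster_association
        drivers = {"ASXL1": 1, "GATA2": 2, "FLT3": 3}
        hits = [g for g in drivers if assoc.loc[g, "q"] < 0.1]
        assert len(hits) >= 2
        for gene in hits:
            assert assoc.loc[gene, "enriched_cluster"] == drivers[gene]
        # passengers stay quiet
        passengers = assoc.index.difference(list(drivers))
        assert (assoc.loc[passengers, "q"] >= 0.1).all()

    def test_requires_two_clusters(self, cohort):
        ones = pd.Series(1, index=cohort.mutations.sample_ids)
        with pytest.raises(ValueError, match="clusters"):
            mutation_analysis(cohort.mutations, ones)


class TestRppaDifferential:
    def test_symmetric_shifts_select_one_up_one_down(self):
        rng = np.random.default_rng(4)
        n = 30
        samples = [f"S{i}" for i in range(2 * n)]
        values = rng.normal(0, 0.1, (12, 2 * n))
        values[0, :n] += 3.0  # up in group A
        values[1, :n] -= 3.0  # down in group A
        prot = ProteinMatrix(pd.DataFrame(
            values, index=[f"P{i}" for i in range(12)], columns=samples))
        res = rppa_differential(prot, samples[:n], samples[n:])
        assert res.table.loc["P0", "selected_up"]
        assert res.table.loc["P1", "selected_down"]
        assert res.table["selected_up"].sum() == 1
        assert res.table["selected_down"].sum() == 1

    def test_null_selects_nothing(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(40)]
        prot = ProteinMatrix(pd.DataFrame(
            rng.normal(size=(20, 40)), index=[f"P{i}" for i in range(20)],
            columns=samples))
        res = rppa_differential(prot, samples[:20], samples[20:])
        assert res.table["selected_up"].sum() == 0
        assert res.table["selected_down"].sum() == 0

    def test_planted_group3_proteins_selected(self, cohort):
        groups = cohort.latent_groups
        g3 = groups.index[groups == 3].tolist()
        g1 = groups.index[groups == 1].tolist()
        res = rppa_differential(cohort.proteins, g3, g1)
        assert res.table.loc["MTOR.pS2448", "selected_up"]
        assert res.table.loc["MCL1", "selected_up"]

    def test_overlapping_groups_rejected(self, cohort):
        ids = cohort.proteins.sample_ids
        with pytest.raises(ValueError, match="overlap"):
            rppa_differential(cohort.proteins, ids[:5], ids[4:9])
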