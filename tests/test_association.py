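"""Contingency tables, chi-square/Fisher tests, odds ratios, t-tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fourlocus import (ContingencyTable, DegenerateTableError, GenotypeCounts,
                       SummaryStats, ValidationError, allele_table,
                       choose_test, fisher_exact, genotype_table,
                       odds_ratio_ci, pearson_chi2, rank_sum,
                       t_test_from_summary)
from fourlocus.loci import ADRB2, IL4


def table2x2(a, b, c, d):
    return ContingencyTable(("asthma", "control"), ("x", "y"),
                            np.array([[a, b], [c, d]], float))


def fisher_two_tailed_oracle(a, b, c, d):
    """Brute-force two-tailed Fisher p: enumerate all tables with the
    observed margins, sum hypergeometric probabilities <= observed's."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestTableBuilders:
    def test_han_adrb2_genotype_table(self, han_counts):
        from fourlocus.cohort import Group
        t = genotype_table(han_counts[Group.ASTHMA]["rs1042713"],
                           han_counts[Group.CONTROL]["rs1042713"])
        assert t.counts.sum(axis=1).tolist() == [101.0, 92.0]
        assert t.col_labels == ("AA", "AG", "GG")

    def test_kazak_il4_row_sums(self, kazak_counts):
        from fourlocus.cohort import Group
        t = genotype_table(kazak_counts[Group.ASTHMA]["rs2243250"],
                           kazak_counts[Group.CONTROL]["rs2243250"])
        assert np.array_equal(t.counts, [[18, 44, 18], [29, 48, 16]])

    def test_identical_counts_give_identical_rows(self):
        c = GenotypeCounts(ADRB2, 10, 20, 5)
        t = genotype_table(c, c)
        assert np.array_equal(t.counts[0], t.counts[1])

    def test_locus_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="different loci"):
            genotype_table(GenotypeCounts(ADRB2, 1, 1, 1),
                           GenotypeCounts(IL4, 1, 1, 1))

    def test_allele_table_conventions(self, han_counts):
        from fourlocus.cohort import Group
        case = han_counts[Group.ASTHMA]["rs1042713"]
        ctrl = han_counts[Group.CONTROL]["rs1042713"]
        per_ind = allele_table(case, ctrl, "per_individual")
        assert np.allclose(per_ind.counts, [[59, 42], [40, 52]])
        two_n = allele_table(case, ctrl, "two_n")
        assert np.allclose(two_n.counts, [[118, 84], [80, 104]])
        assert np.allclose(two_n.counts, 2 * per_ind.counts)

    def test_monomorphic_locus_is_untestable(self):
        case = GenotypeCounts(ADRB2, 10, 0, 0)
        ctrl = GenotypeCounts(ADRB2, 8, 0, 0)
        t = allele_table(case, ctrl, "two_n")
        assert t.counts[0, 1] == t.counts[1, 1] == 0  # zero column
        with pytest.raises(DegenerateTableError):
            pearson_chi2(t)


class TestPearsonChi2:
    def test_han_adrb2_genotype_statistic(self, han_counts):
        from fourlocus.cohort import Group
        t = genotype_table(han_counts[Group.ASTHMA]["rs1042713"],
                           han_counts[Group.CONTROL]["rs1042713"])
        res = pearson_chi2(t)
        assert round(res.statistic, 2) == 11.09
        assert res.df == 2
        assert round(res.p_value, 3) == 0.004

    def test_han_adrb2_allele_statistic(self, han_counts):
        from fourlocus.cohort import Group
        t = allele_table(han_counts[Group.ASTHMA]["rs1042713"],
                         han_counts[Group.CONTROL]["rs1042713"],
                         "per_individual")
        res = pearson_chi2(t)
        assert round(res.statistic, 2) == 4.30
        assert res.df == 1

    def test_proportional_rows_independent(self):
        t = ContingencyTable(("a", "b"), ("x", "y", "z"),
                             np.array([[10, 20, 30], [20, 40, 60]], float))
        res = pearson_chi2(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_kazak_risk_class_p(self):
        res = pearson_chi2(table2x2(15, 65, 16, 77))
        assert round(res.p_value, 2) == 0.79

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2(table2x2(0, 5, 0, 7))

    def test_yates_reduces_statistic_2x2_only(self):
        plain = pearson_chi2(table2x2(12, 5, 6, 14))
        corrected = pearson_chi2(table2x2(12, 5, 6, 14), yates=True)
        assert corrected.statistic < plain.statistic
        assert corrected.method == "pearson_yates"
        t23 = ContingencyTable(("a", "b"), ("x", "y", "z"),
                               np.array([[1, 2, 3], [4, 5, 6]], float))
        with pytest.raises(ValidationError):
            pearson_chi2(t23, yates=True)

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50), st.integers(2, 9))
    @settings(max_examples=50, deadline=None)
    def test_linear_scaling_and_permutation_invariance(self, a, b, c, d, k):
        base = pearson_chi2(table2x2(a, b, c, d)).statistic
        scaled = pearson_chi2(table2x2(k * a, k * b, k * c, k * d)).statistic
        assert scaled == pytest.approx(k * base, rel=1e-9)
        swapped = pearson_chi2(table2x2(c, d, a, b)).statistic
        assert swapped == pytest.approx(base, rel=1e-9)
        half = pearson_chi2(table2x2(a / 2, b / 2, c / 2, d / 2)).statistic
        assert half == pytest.approx(base / 2, rel=1e-9)


class TestFisherExact:
    @pytest.mark.parametrize("cells,expected_p", [
        ((2, 8, 8, 2), 0.023),
        ((5, 5, 5, 5), 1.0),
    ])
    def test_examples_against_enumeration_oracle(self, cells, expected_p):
        res = fisher_exact(table2x2(*cells))
        assert round(res.p_value, 3) == pytest.approx(expected_p, abs=5e-4)
        assert res.p_value == pytest.approx(fisher_two_tailed_oracle(*cells),
                                            rel=1e-6)

    def test_extreme_table_tail(self):
        res = fisher_exact(table2x2(0, 10, 10, 0))
        assert res.p_value < 1e-4
        # one-sided tail equals the direct hypergeometric point mass here
        assert res.p_value == pytest.approx(
            fisher_two_tailed_oracle(0, 10, 10, 0), rel=1e-6)

    def test_statistic_is_observed_table_probability(self):
        res = fisher_exact(table2x2(2, 8, 8, 2))
        assert res.statistic == pytest.approx(
            stats.hypergeom.pmf(2, 20, 10, 10), rel=1e-9)

    def test_non_integral_table_rejected(self):
        with pytest.raises(ValidationError, match="two_n"):
            fisher_exact(table2x2(1.5, 2.5, 3.0, 4.0))

    @given(st.integers(5, 60), st.integers(5, 60), st.integers(5, 60),
           st.integers(5, 60))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_pearson_near_significance(self, a, b, c, d):
        # With all expected counts >= 5 the exact and asymptotic tests track
        # each other wherever either approaches significance; deep in the
        # null region Fisher's two-sided p is discrete and may sit far from
        # the chi-square p without changing any conclusion.
        t = table2x2(a, b, c, d)
        if np.any(t.expected() < 5):
            return
        p_f = fisher_exact(t).p_value
        p_p = pearson_chi2(t).p_value
        if min(p_f, p_p) < 0.05:
            assert abs(p_f - p_p) < 0.05
        assert not ((p_f < 0.01) != (p_p < 0.01)
                    and (p_f > 0.10 or p_p > 0.10))


class TestOddsRatio:
    @pytest.mark.parametrize("cells,expected", [
        ((45, 56, 22, 70), (2.56, 1.38, 4.75)),
        ((15, 65, 16, 77), (1.11, 0.51, 2.42)),
    ])
    def test_published_woolf_intervals(self, cells, expected):
        res = odds_ratio_ci(table2x2(*cells))
        got = (round(res.odds_ratio, 2), round(res.ci_low, 2),
               round(res.ci_high, 2))
        assert got == expected

    def test_cross_check_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        t = sm.Table2x2(np.array([[45, 56], [22, 70]]))
        res = odds_ratio_ci(table2x2(45, 56, 22, 70))
        assert res.odds_ratio == pytest.approx(t.oddsratio, rel=1e-9)
        lo, hi = t.oddsratio_confint(0.05)
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)

    @pytest.mark.parametrize("k", [1, 5, 40])
    def test_balanced_table_symmetric_about_one(self, k):
        res = odds_ratio_ci(table2x2(k, k, k, k))
        assert res.odds_ratio == pytest.approx(1.0)
        assert math.log(res.ci_low) == pytest.approx(-math.log(res.ci_high))

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(1, 60),
           st.integers(1, 60))
    @settings(max_examples=50, deadline=None)
    def test_exposure_inversion_reciprocates(self, a, b, c, d):
        fwd = odds_ratio_ci(table2x2(a, b, c, d))
        rev = odds_ratio_ci(table2x2(b, a, d, c))
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio, rel=1e-9)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high, rel=1e-9)
        assert rev.ci_high == pytest.approx(1 / fwd.ci_low, rel=1e-9)

    def test_zero_cell_requires_haldane_opt_in(self):
        with pytest.raises(DegenerateTableError, match="Haldane"):
            odds_ratio_ci(table2x2(0, 10, 5, 5))
        res = odds_ratio_ci(table2x2(0, 10, 5, 5), haldane=True)
        assert 0 < res.odds_ratio < 1


class TestTTest:
    def test_han_age_comparison(self):
        res = t_test_from_summary(SummaryStats(6.48, 2.38, 101),
                                  SummaryStats(5.74, 3.70, 92), "pooled")
        assert round(res.p_value, 3) == 0.097
        assert res.df == 191

    def test_kazak_age_comparison(self):
        res = t_test_from_summary(SummaryStats(4.89, 3.63, 80),
                                  SummaryStats(4.98, 3.37, 93), "pooled")
        assert 0.85 <= res.p_value <= 0.87

    def test_identical_summaries_null(self):
        s = SummaryStats(5.0, 2.0, 30)
        res = t_test_from_summary(s, s)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_welch_satterthwaite_df(self):
        res = t_test_from_summary(SummaryStats(6.48, 2.38, 101),
                                  SummaryStats(5.74, 3.70, 92), "welch")
        assert res.variant == "welch"
        assert res.df < 101 + 92 - 2  # Welch df never exceeds pooled df


class TestUtilities:
    def test_rank_sum_matches_scipy(self):
        a = [1.2, 3.4, 2.2, 5.6, 4.4]
        b = [2.1, 6.3, 7.7, 5.5, 8.8, 9.1]
        u, p = rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        assert (u, p) == (ref.statistic, ref.pvalue)

    def test_choose_test_selects_fisher_for_sparse_2x2(self):
        sparse = table2x2(1, 9, 8, 2)
        assert choose_test(sparse).method == "fisher"
        dense = table2x2(30, 40, 35, 45)
        assert choose_test(dense).method == "pearson"
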