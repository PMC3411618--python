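"""Frequency tables, Monte-Carlo clump tests and odds ratios."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dla_hapassoc import reference_data as ref
from dla_hapassoc.association import (
    ClumpVariant,
    ExposureLevel,
    FilterScope,
    FrequencyTable,
    TwoByTwo,
    bonferroni_threshold,
    build_allele_table,
    build_haplotype_table,
    carrier_table,
    chi_squared_statistic,
    chromosome_table,
    clump_partition,
    clump_test,
    filter_by_frequency,
    odds_ratio,
)
from dla_hapassoc.errors import (
    DegenerateTableError,
    PhasingError,
    ValidationError,
)
from dla_hapassoc.genotypes import Cohort, Locus, Status
from dla_hapassoc.phasing import PhasingResult, assign_all


class TestTables:
    def test_allele_table_margins(self, fixture_cohort):
        table = build_allele_table(fixture_cohort.cohort, Locus.DRB1)
        assert sum(table.case_counts) == table.case_total == 132
        assert sum(table.control_counts) == table.control_total == 168
        assert table.count_pair("01501") == (50, 68)

    def test_single_homozygous_dog_frequency_one(self):
        from dla_hapassoc.genotypes import Diplotype, Haplotype
        h = Haplotype("01501", "00601", "00301")
        rec = Diplotype(h, h).to_genotypes(Status.CASE, "d1")
        table = build_allele_table(Cohort([rec]), Locus.DRB1)
        assert table.case_frequencies == (1.0,)

    def test_haplotype_table_counts(self, fixture_cohort, phased):
        table = build_haplotype_table(phased, fixture_cohort.cohort)
        assert table.count_pair(ref.RISK_HAPLOTYPE.label) == (19, 11)
        assert table.count_pair(ref.PROTECTIVE_HAPLOTYPE.label) == (4, 20)

    def test_homozygote_contributes_two_chromosomes(self):
        from dla_hapassoc.genotypes import Diplotype, Haplotype
        h = Haplotype("00601", "005011", "00701")
        rec = Diplotype(h, h).to_genotypes(Status.CASE, "d1")
        cohort = Cohort([rec])
        res = assign_all(cohort)
        table = build_haplotype_table(res, cohort)
        assert table.count_pair(h.label) == (2, 0)

    def test_unresolved_dogs_rejected_unless_allowed(self, fixture_cohort):
        res = PhasingResult(assignments={
            r.dog_id: None for r in fixture_cohort.cohort})
        with pytest.raises(PhasingError):
            build_haplotype_table(res, fixture_cohort.cohort)
        table = build_haplotype_table(res, fixture_cohort.cohort,
                                      allow_unresolved=True)
        assert len(table) == 0


class TestFilter:
    def test_either_group_retains_eleven(self, fixture_cohort, phased):
        table = build_haplotype_table(phased, fixture_cohort.cohort)
        kept = filter_by_frequency(table, 0.01, FilterScope.EITHER_GROUP)
        assert len(kept) == 11

    def test_pooled_scope_retains_ten(self, haplotype_published_table):
        kept = filter_by_frequency(haplotype_published_table, 0.01,
                                   FilterScope.POOLED)
        assert len(kept) == 10

    def test_zero_threshold_is_identity(self, haplotype_published_table):
        out = filter_by_frequency(haplotype_published_table, 0.0)
        assert out == haplotype_published_table

    def test_pooling_preserves_column_sums(self, haplotype_published_table):
        out = filter_by_frequency(haplotype_published_table, 0.01,
                                  FilterScope.POOLED, pool_other=True)
        assert sum(out.case_counts) == 132
        assert sum(out.control_counts) == 168
        assert out.categories[-1].startswith("other")


class TestChiSquared:
    def test_identical_distributions_give_zero(self):
        t = FrequencyTable.from_counts(
            [("a", 10, 10), ("b", 30, 30), ("c", 5, 5)])
        assert chi_squared_statistic(t) == pytest.approx(0.0)

    def test_fully_separated_two_by_two(self):
        t = FrequencyTable.from_counts([("a", 10, 0), ("b", 0, 10)])
        assert chi_squared_statistic(t) == pytest.approx(20.0)

    def test_matches_scipy_on_published_table(self, drb1_published_table):
        obs = drb1_published_table.to_arrays()
        expected = stats.chi2_contingency(obs, correction=False).statistic
        assert chi_squared_statistic(drb1_published_table) \
            == pytest.approx(expected)

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_squared_statistic(FrequencyTable.from_counts([("a", 5, 5)]))


def exact_conditional_p(table: FrequencyTable) -> float:
    """Exact tail probability of the Pearson statistic over all 2xn
    tables with both margins fixed (enumeration oracle, tiny n only)."""
    totals = table.pooled_counts
    n_case = sum(table.case_counts)
    n = n_case + sum(table.control_counts)
    obs = chi_squared_statistic(table)
    p = 0.0
    denom = math.comb(n, n_case)
    for combo in itertools.product(*(range(t + 1) for t in totals)):
        if sum(combo) != n_case:
            continue
        weight = math.prod(math.comb(t, a) for t, a in zip(totals, combo))
        t2 = FrequencyTable.from_counts([
            (c, a, t - a)
            for c, t, a in zip(table.categories, totals, combo)])
        if chi_squared_statistic(t2) >= obs - 1e-9:
            p += weight / denom
    return p


class TestClump:
    def test_empirical_p_matches_enumeration_oracle(self):
        """MC p within 3 Monte-Carlo SE of the exact conditional p on a
        small 2x3 table."""
        t = FrequencyTable.from_counts(
            [("a", 8, 2), ("b", 3, 7), ("c", 4, 6)])
        exact = exact_conditional_p(t)
        res = clump_test(t, ClumpVariant.T1_ALL, n_trials=40_000, seed=5)
        se = math.sqrt(exact * (1 - exact) / res.n_trials)
        assert abs(res.p_empirical - exact) <= 3 * se + 1 / res.n_trials

    def test_equal_tables_give_p_one(self):
        t = FrequencyTable.from_counts([("a", 20, 20), ("b", 30, 30)])
        res = clump_test(t, ClumpVariant.T1_ALL, n_trials=2000, seed=1)
        assert res.statistic_observed == pytest.approx(0.0)
        assert res.p_empirical > 0.95

    def test_fixed_seed_bit_identical(self, drb1_published_table):
        r1 = clump_test(drb1_published_table, ClumpVariant.T2_CLUMPED,
                        5000, seed=42)
        r2 = clump_test(drb1_published_table, ClumpVariant.T2_CLUMPED,
                        5000, seed=42)
        assert r1 == r2

    def test_p_always_in_unit_interval(self, drb1_published_table):
        res = clump_test(drb1_published_table, ClumpVariant.T1_ALL,
                         n_trials=1, seed=0)
        assert 0 < res.p_empirical <= 1

    def test_t1_matches_asymptotic_tail_when_cells_large(self):
        """With large expected counts the conditional MC p agrees with the
        asymptotic chi-squared tail within 3 MC standard errors.

        Cell counts in the hundreds: below that the lattice discreteness
        of the margin-fixed null (the tie atom at the observed statistic)
        exceeds pure Monte-Carlo error and the asymptotic comparison is
        not a clean oracle.
        """
        t = FrequencyTable.from_counts(
            [("a", 275, 225), ("b", 240, 260), ("c", 252, 248),
             ("d", 233, 267)])
        stat = chi_squared_statistic(t)
        asym = stats.chi2.sf(stat, df=3)
        res = clump_test(t, ClumpVariant.T1_ALL, n_trials=60_000, seed=11)
        se = math.sqrt(asym * (1 - asym) / res.n_trials)
        assert abs(res.p_empirical - asym) <= 3 * se

    def test_clump_partition_pools_until_expected_reaches_five(
            self, drb1_published_table, haplotype_published_table):
        part = clump_partition(drb1_published_table)
        clumped = {c for c, g in part.items() if g == "clumped"}
        # the four sparse alleles have expected < 5; pooled they still
        # fall short, so the next-smallest (00101) joins the clump
        assert clumped == {"00901", "01502", "02301", "012v", "00101"}
        part2 = clump_partition(haplotype_published_table)
        clumped2 = {c for c, g in part2.items() if g == "clumped"}
        assert len(haplotype_published_table) - len(clumped2) == 7

    def test_degenerate_after_clumping_rejected(self):
        t = FrequencyTable.from_counts([("a", 2, 1), ("b", 1, 2)])
        with pytest.raises(DegenerateTableError):
            clump_test(t, ClumpVariant.T2_CLUMPED, 100, seed=0)


class TestOddsRatio:
    @pytest.mark.parametrize("cells,expected", [
        ((4, 128, 20, 148), 0.23),     # protective DRB1 allele
        ((19, 113, 11, 157), 2.40),    # risk DRB1 allele
        ((5, 127, 20, 148), 0.29),     # protective DQB1 allele
        ((18, 48, 9, 75), 3.13),       # risk haplotype, carrier level
        ((1, 1, 1, 1), 1.0),
    ])
    def test_point_estimates(self, cells, expected):
        res = odds_ratio(TwoByTwo(*cells))
        assert res.point == pytest.approx(expected, abs=0.005)

    def test_reciprocity(self):
        t = TwoByTwo(19, 113, 11, 157)
        assert odds_ratio(t).point * odds_ratio(t.swapped()).point \
            == pytest.approx(1.0)

    def test_woolf_interval_brackets_point(self):
        res = odds_ratio(TwoByTwo(19, 113, 11, 157))
        assert res.ci_low < res.point < res.ci_high
        se = math.sqrt(1 / 19 + 1 / 113 + 1 / 11 + 1 / 157)
        assert res.ci_high / res.point \
            == pytest.approx(math.exp(1.96 * se), rel=1e-3)

    def test_zero_cell_haldane_corrected(self):
        res = odds_ratio(TwoByTwo(0, 10, 5, 5))
        assert res.haldane_corrected
        assert res.point == pytest.approx(0.5 * 5.5 / (10.5 * 5.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            TwoByTwo(-1, 1, 1, 1)


class TestCarrierTables:
    def test_risk_haplotype_carriers(self, fixture_cohort, phased):
        t = carrier_table(phased, fixture_cohort.cohort, ref.RISK_HAPLOTYPE)
        assert (t.a, t.b, t.c, t.d) == (18, 48, 9, 75)
        assert t.level is ExposureLevel.CARRIER

    def test_protective_haplotype_carriers(self, fixture_cohort, phased):
        t = carrier_table(phased, fixture_cohort.cohort,
                          ref.PROTECTIVE_HAPLOTYPE)
        assert (t.a, t.b, t.c, t.d) == (4, 62, 20, 64)

    def test_absent_haplotype(self, fixture_cohort, phased):
        from dla_hapassoc.genotypes import Haplotype
        t = carrier_table(phased, fixture_cohort.cohort,
                          Haplotype("99901", "99901", "99901"))
        assert (t.a, t.b, t.c, t.d) == (0, 66, 0, 84)


@pytest.mark.parametrize("alpha,n,expected", [
    (0.05, 3, 0.05 / 3),
    (0.05, 1, 0.05),
])
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected)


def test_chromosome_two_by_two_margins():
    t = FrequencyTable.from_counts(ref.DRB1_ALLELE_COUNTS)
    two = chromosome_table(t, "00501")
    assert two.a + two.b == 132 and two.c + two.d == 168
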