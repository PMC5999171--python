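"""Contingency-table tests, Mann-Whitney, and Table-1-style summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynchpred import (Cohort, ContingencyTable, ValidationError,
                       chi_square_test, dispatch_frequency_test, fisher_exact,
                       mann_whitney_u, summarize_cohort)

from conftest import make_patient


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = hyper(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(hyper(x) for x in range(lo, hi + 1)
               if hyper(x) <= p_obs * (1 + 1e-12))


class TestChiSquare:
    def test_multiple_crc_contrast_reproduces_printed_p(self):
        # 66 of 651 vs 17 of 83 with two or more CRCs
        stat, p = chi_square_test(ContingencyTable(((66, 585), (17, 66))))
        assert round(p, 3) == 0.005

    def test_proportional_table_gives_zero_statistic(self):
        stat, p = chi_square_test(ContingencyTable(((20, 40), (10, 20))))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        table = ContingencyTable(((12, 8), (5, 15)))
        arr = np.array([[12, 8], [5, 15]], float)
        exp = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
        expected_stat = ((arr - exp) ** 2 / exp).sum()
        stat, _ = chi_square_test(table)
        assert stat == pytest.approx(expected_stat, abs=1e-12)

    def test_invariant_under_transposition(self):
        t = ContingencyTable(((7, 13), (22, 4)))
        tt = ContingencyTable(((7, 22), (13, 4)))
        assert chi_square_test(t)[0] == pytest.approx(chi_square_test(tt)[0], abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_test(ContingencyTable(((0, 0), (3, 4))))


class TestFisherExact:
    def test_matches_enumeration_oracle(self):
        table = ((1, 9), (11, 3))
        assert fisher_exact(ContingencyTable(table)) == pytest.approx(
            fisher_enumeration_oracle(table), abs=1e-12)

    def test_symmetric_table_p_one(self):
        assert fisher_exact(ContingencyTable(((5, 5), (5, 5)))) == pytest.approx(1.0)

    def test_male_gender_contrast_matches_printed_p_via_dispatch(self):
        # 305 of 651 vs 6 of 12 male: expected counts all >= 5 -> chi-square
        table = ContingencyTable(((305, 346), (6, 6)))
        test, p = dispatch_frequency_test(table)
        assert test == "chi-square"
        assert round(p, 2) == 0.83

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_enumeration_property_small_tables(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        if a + b + c + d > 40:
            return
        table = ((a, b), (c, d))
        assert fisher_exact(ContingencyTable(table)) == pytest.approx(
            fisher_enumeration_oracle(table), abs=1e-9)

    def test_dispatch_small_expected_uses_fisher(self):
        # expected counts include 10*3/15 = 2 < 5
        table = ContingencyTable(((1, 9), (2, 3)))
        test, _ = dispatch_frequency_test(table)
        assert test == "fisher"


class TestMannWhitney:
    def test_identical_groups(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_exact_enumeration_small_disjoint_groups(self):
        u, p = mann_whitney_u([1, 2], [10, 20])
        assert u == 0.0
        # all C(4,2)=6 rank splits; only the two extreme ones are as extreme
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_normal_approximation_matches_hand_formula(self):
        rng = np.random.default_rng(77)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        u, p = mann_whitney_u(a, b)
        # independent implementation: tie-corrected normal approximation
        combined = np.concatenate([a, b])
        order = combined.argsort()
        ranks = np.empty_like(combined)
        ranks[order] = np.arange(1, 61)
        # midranks for ties
        for v in np.unique(combined):
            mask = combined == v
            ranks[mask] = ranks[mask].mean()
        n1, n2 = 30, 30
        u1 = ranks[:30].sum() - n1 * (n1 + 1) / 2
        u_stat = u1
        _, counts = np.unique(combined, return_counts=True)
        tie_term = (counts ** 3 - counts).sum()
        n = n1 + n2
        sigma = math.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1))))
        z = (u_stat - n1 * n2 / 2) / sigma
        from scipy.stats import norm
        expected_p = 2 * norm.sf(abs(z))
        assert p == pytest.approx(expected_p, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


def _table1_like_cohort():
    """Deterministic cohort hitting exact marginal counts for key cells.

    651 non-carriers: 185 proximal, 305 male, 11 of the 346 women with EC.
    83 carriers: 53 proximal, 41 male, 17 of the 42 women with EC.
    """
    patients = []
    i = 0

    def add(n, status, proximal, male, ec):
        nonlocal i
        for _ in range(n):
            patients.append(make_patient(
                id=f"T{i}", sex="male" if male else "female",
                any_proximal_crc=proximal, ec=ec,
                age_ec=60.0 if ec else None,
                mutation_status=status))
            i += 1

    # non-carriers: distribute proximal across sexes (counts matter, joint doesn't)
    add(185, "none", True, True, False)
    add(120, "none", False, True, False)
    add(11, "none", False, False, True)
    add(335, "none", False, False, False)
    # carriers (status MLH1 as representative): 41 male + 42 female,
    # 36 + 17 = 53 proximal, 17 of the women with EC
    add(36, "MLH1", True, True, False)
    add(5, "MLH1", False, True, False)
    add(17, "MLH1", True, False, True)
    add(25, "MLH1", False, False, False)
    return Cohort(patients).validate()


class TestSummarizeCohort:
    def test_reproduces_exact_marginal_cells(self):
        df = summarize_cohort(_table1_like_cohort(), "all_carriers")
        rows = df.set_index("variable")
        assert rows.loc["Proximal CRC", "negative"] == "28% (185)"
        assert rows.loc["Proximal CRC", "positive"] == "64% (53)"
        assert rows.loc["Male gender", "negative"] == "47% (305)"
        # EC among women only: 11/346 and 17/42
        assert rows.loc["Endometrial cancer", "negative"] == "3% (11)"
        assert rows.loc["Endometrial cancer", "positive"] == "40% (17)"

    def test_single_variable_toy_cohort_counts(self):
        patients = [make_patient(id=f"A{i}", any_proximal_crc=(i < 2),
                                 mutation_status="none") for i in range(4)]
        patients += [make_patient(id=f"B{i}", any_proximal_crc=True,
                                  mutation_status="MSH2") for i in range(2)]
        df = summarize_cohort(Cohort(patients).validate(), "all_carriers")
        rows = df.set_index("variable")
        assert rows.loc["Proximal CRC", "negative"] == "50% (2)"
        assert rows.loc["Proximal CRC", "positive"] == "100% (2)"

    def test_pms2_contrast_requires_pms2_carriers(self):
        cohort = Cohort([make_patient(id="X", mutation_status="none"),
                         make_patient(id="Y", mutation_status="MLH1")])
        with pytest.raises(ValidationError):
            summarize_cohort(cohort, "pms2_only")

    def test_per_row_test_dispatch_recorded(self, medium_cohort):
        df = summarize_cohort(medium_cohort, "all_carriers")
        used = set(df["test"]) - {""}
        assert used <= {"chi-square", "fisher", "mann-whitney", "-"}
        assert "mann-whitney" in used and ("chi-square" in used or "fisher" in used)
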