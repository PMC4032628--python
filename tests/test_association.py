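"""Fisher machinery against independent enumeration oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarevar.association import (
    ContingencyTable,
    associate,
    bonferroni,
    fisher_right,
    odds_ratio_ci,
    sample_odds_ratio,
)
from rarevar.errors import DomainError


def log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(a: int, n_cases: int, n_controls: int, carriers: int) -> float:
    """Independent hypergeometric pmf from log-factorials."""
    if a < max(0, carriers - n_controls) or a > min(carriers, n_cases):
        return 0.0
    return math.exp(
        log_choose(n_cases, a)
        + log_choose(n_controls, carriers - a)
        - log_choose(n_cases + n_controls, carriers)
    )


def right_tail_by_enumeration(table: ContingencyTable) -> float:
    return sum(
        hypergeom_pmf(x, table.n_cases, table.n_controls, table.n_carriers)
        for x in range(table.a, min(table.n_carriers, table.n_cases) + 1)
    )


class TestFisherRight:
    @pytest.mark.parametrize(
        "table, printed",
        [
            (ContingencyTable(16, 2180, 12, 3377), 0.042),
            (ContingencyTable(17, 2179, 9, 3380), 0.006),
            (ContingencyTable(14, 2182, 9, 3380), 0.030),
            (ContingencyTable(12, 2184, 8, 3381), 0.049),
            (ContingencyTable(6, 2190, 1, 3388), 0.017),
        ],
    )
    def test_study_tables_round_to_printed_p(self, table, printed):
        assert round(fisher_right(table), 3) == printed

    def test_no_carriers_gives_one(self):
        assert fisher_right(ContingencyTable(0, 50, 0, 80)) == 1.0

    def test_matches_enumeration_on_fixture_margins(self):
        table = ContingencyTable(17, 2179, 9, 3380)
        assert fisher_right(table) == pytest.approx(
            right_tail_by_enumeration(table), rel=1e-10
        )

    @settings(max_examples=150, deadline=None)
    @given(
        n_cases=st.integers(5, 300),
        n_controls=st.integers(5, 300),
        carriers=st.integers(0, 40),
        data=st.data(),
    )
    def test_agrees_with_enumeration(self, n_cases, n_controls, carriers, data):
        carriers = min(carriers, n_cases + n_controls)
        a = data.draw(
            st.integers(max(0, carriers - n_controls), min(carriers, n_cases))
        )
        table = ContingencyTable(a, n_cases - a, carriers - a, n_controls - (carriers - a))
        assert fisher_right(table) == pytest.approx(
            right_tail_by_enumeration(table), rel=1e-9, abs=1e-12
        )

    def test_monotone_decreasing_in_a(self):
        prev = 2.0
        for a in range(0, 21):
            p = fisher_right(ContingencyTable(a, 100 - a, 20 - a, 180 - (20 - a)))
            assert p <= prev + 1e-15
            prev = p

    def test_tail_identity(self):
        """P(right) + P(strict left) - P(observed) = 1 by enumeration."""
        t = ContingencyTable(7, 43, 5, 95)
        left_strict = sum(
            hypergeom_pmf(x, t.n_cases, t.n_controls, t.n_carriers)
            for x in range(0, t.a + 1)
        )
        obs = hypergeom_pmf(t.a, t.n_cases, t.n_controls, t.n_carriers)
        assert fisher_right(t) + left_strict - obs == pytest.approx(1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(DomainError):
            ContingencyTable(-1, 10, 2, 10)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table, printed",
        [
            (ContingencyTable(16, 2180, 12, 3377), 2.065),
            (ContingencyTable(17, 2179, 9, 3380), 2.930),
            (ContingencyTable(14, 2182, 9, 3380), 2.410),
            (ContingencyTable(12, 2184, 8, 3381), 2.322),
            (ContingencyTable(6, 2190, 1, 3388), 9.282),
        ],
    )
    def test_study_cross_product_values(self, table, printed):
        assert sample_odds_ratio(table) == pytest.approx(printed, abs=5e-4)

    def test_symmetric_table_is_one(self):
        assert sample_odds_ratio(ContingencyTable(3, 50, 3, 50)) == 1.0

    def test_zero_control_carriers_is_infinite(self):
        assert sample_odds_ratio(ContingencyTable(4, 96, 0, 100)) == math.inf

    def test_degenerate_table_rejected(self):
        with pytest.raises(DomainError):
            sample_odds_ratio(ContingencyTable(0, 100, 0, 100))


def conditional_ci_oracle(table, level=0.95, tol=1e-6):
    """Bisection over the noncentral hypergeometric tails, built directly
    on the unnormalised pmf (independent of the implementation path)."""
    a, n1, n2, K = table.a, table.n_cases, table.n_controls, table.n_carriers
    lo_supp, hi_supp = max(0, K - n2), min(K, n1)

    def tail(psi, upper):
        logs = [
            log_choose(n1, x) + log_choose(n2, K - x) + x * math.log(psi)
            for x in range(lo_supp, hi_supp + 1)
        ]
        peak = max(logs)
        weights = [math.exp(l - peak) for l in logs]
        total = sum(weights)
        if upper:
            return sum(weights[a - lo_supp:]) / total
        return sum(weights[: a - lo_supp + 1]) / total

    alpha = (1 - level) / 2

    def bisect(func, target):
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if func(mid) > target:
                hi = mid
            else:
                lo = mid
        return math.sqrt(lo * hi)

    low = 0.0 if a == lo_supp else bisect(lambda s: tail(s, True), alpha)
    high = math.inf if a == hi_supp else bisect(lambda s: 1 - tail(s, False), 1 - alpha)
    return low, high


class TestConfidenceIntervals:
    def test_woolf_contains_sample_or(self):
        t = ContingencyTable(16, 2180, 12, 3377)
        lo, hi = odds_ratio_ci(t, 0.95, "woolf_log")
        assert lo < sample_odds_ratio(t) < hi

    def test_exact_conditional_matches_bisection_oracle(self):
        t = ContingencyTable(16, 2180, 12, 3377)
        lo, hi = odds_ratio_ci(t, 0.95, "exact_conditional")
        olo, ohi = conditional_ci_oracle(t)
        assert lo == pytest.approx(olo, abs=1e-4)
        assert hi == pytest.approx(ohi, abs=1e-4)

    def test_both_methods_cover_one_on_null_table(self):
        t = ContingencyTable(1, 9, 1, 9)
        for method in ("woolf_log", "exact_conditional"):
            lo, hi = odds_ratio_ci(t, 0.95, method)
            assert lo < 1.0 < hi

    def test_zero_cell_handled_by_haldane(self):
        lo, hi = odds_ratio_ci(ContingencyTable(4, 96, 0, 100), 0.95, "woolf_log")
        assert 0 < lo < hi < math.inf


class TestBonferroni:
    def test_study_doubled_burden_p(self):
        # the published corrected value is twice the published per-test
        # P (2 x 0.042 = 0.084); the unrounded doubled P is 0.0845
        p = fisher_right(ContingencyTable(16, 2180, 12, 3377))
        assert round(p, 3) == 0.042
        assert bonferroni(round(p, 3), 2) == 0.084
        assert bonferroni(p, 2) == pytest.approx(0.0845, abs=5e-4)

    def test_capped_at_one(self):
        assert bonferroni(0.9, 2) == 1.0

    def test_identity_at_m_one(self):
        assert bonferroni(0.123, 1) == 0.123


def test_associate_bundles_consistently():
    res = associate(ContingencyTable(16, 2180, 12, 3377), bonferroni_m=2)
    assert res.p_corrected == pytest.approx(min(1.0, 2 * res.p_right))
    assert res.ci_low < res.odds_ratio < res.ci_high
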