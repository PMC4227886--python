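"""Normalization, revision rules, fold changes and the two-library
count-comparison statistic."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from srnapipe.expression import (CountPair, GeneCount, build_rows, call_dem,
                                 call_deg, fold_change, rank_top,
                                 revise_and_filter, rpkm, rpm, rows_to_frame,
                                 two_library_pvalue, ExpressionRow)
from srnapipe.tables import load_deg_table, load_dem_table


def exact_pvalue(x, y, n1, n2):
    """Arbitrary-precision two-sided tail of p(y|x) (rational oracle)."""
    r = Fraction(n2, n1)

    def pmf(k):
        return (r ** k * math.comb(x + k, k)
                / (1 + r) ** (x + k + 1))

    lower = sum(pmf(k) for k in range(0, y + 1))
    upper = 1 - lower + pmf(y)
    return float(min(1, 2 * min(lower, upper)))


class TestNormalization:
    def test_rpm_identities(self):
        assert rpm(0, 100) == 0
        assert rpm(100, 100) == 1e6
        assert rpm(37, 10 ** 6) == 37.0

    def test_rpm_rejects_zero_total(self):
        with pytest.raises(ValueError):
            rpm(1, 0)

    def test_rpkm_arithmetic(self):
        assert rpkm(GeneCount(C=1000, N=10 ** 6, L=1000)) == 1000.0
        assert rpkm(GeneCount(C=0, N=10 ** 6, L=500)) == 0.0

    def test_rpkm_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(10 ** 4, 10 ** 7))
            c = int(rng.integers(0, 10 ** 4))
            length = int(rng.integers(100, 10 ** 4))
            assert rpkm(GeneCount(C=c, N=n, L=length)) == \
                pytest.approx(1e9 * c / (n * length))

    def test_gene_count_invariants(self):
        with pytest.raises(ValueError):
            GeneCount(C=10, N=5, L=100)
        with pytest.raises(ValueError):
            GeneCount(C=1, N=5, L=0)


class TestReviseAndFilter:
    def test_zero_treated_revised(self):
        assert revise_and_filter(2.3, 0) == ((2.3, 0.01), False)

    def test_zero_control_revised(self):
        assert revise_and_filter(0, 1.9) == ((0.01, 1.9), False)

    def test_both_below_one_excluded(self):
        (_pair, excluded) = revise_and_filter(0.5, 0.8)
        assert excluded

    def test_one_above_one_not_excluded(self):
        assert revise_and_filter(0.5, 1.2)[1] is False

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            revise_and_filter(-1, 2)


class TestFoldChange:
    def test_printed_ratio_up(self):
        f = fold_change((35.3, 63.9))
        assert f == pytest.approx(1.8102, abs=1e-4)
        assert round(f, 1) == 1.8

    def test_printed_ratio_after_revision(self):
        pair, _ = revise_and_filter(2.3, 0)
        assert round(fold_change(pair), 3) == 0.004

    def test_swapping_conditions_gives_reciprocal(self):
        assert fold_change((4.0, 10.0)) == pytest.approx(
            1 / fold_change((10.0, 4.0)))


class TestTwoLibraryPvalue:
    def test_equal_counts_equal_totals_give_one(self):
        p = two_library_pvalue(CountPair(x=10, y=10, N1=10 ** 6, N2=10 ** 6))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_exact_oracle(self):
        cases = [(50, 0, 10 ** 6, 10 ** 6), (0, 50, 10 ** 6, 10 ** 6),
                 (5, 25, 10 ** 5, 2 * 10 ** 5), (100, 80, 10 ** 6, 10 ** 6),
                 (3, 3, 10 ** 4, 3 * 10 ** 4)]
        for x, y, n1, n2 in cases:
            got = two_library_pvalue(CountPair(x=x, y=y, N1=n1, N2=n2))
            assert got == pytest.approx(exact_pvalue(x, y, n1, n2), abs=1e-9)

    def test_pmf_normalizes(self):
        x, n1, n2 = 40, 10 ** 6, 10 ** 6
        r = Fraction(n2, n1)
        K = x + int(40 * math.sqrt(x)) + 100
        total = sum(r ** k * math.comb(x + k, k) / (1 + r) ** (x + k + 1)
                    for k in range(K + 1))
        assert float(total) >= 1 - 1e-9

    def test_depends_on_library_ratio_only(self):
        """The statistic conditions on the observed counts and the library
        size ratio N2/N1; jointly rescaling both totals leaves P
        unchanged."""
        rng = np.random.default_rng(6)
        for _ in range(25):
            x, y = int(rng.integers(0, 300)), int(rng.integers(0, 300))
            n1 = int(rng.integers(10 ** 4, 10 ** 5))
            n2 = int(rng.integers(10 ** 4, 10 ** 5))
            a = two_library_pvalue(CountPair(x=x, y=y, N1=n1, N2=n2))
            b = two_library_pvalue(CountPair(x=x, y=y, N1=7 * n1, N2=7 * n2))
            assert a == pytest.approx(b, abs=1e-12)

    def test_orientation_is_fixed_by_the_conditioning(self):
        """The test conditions on the control count x and evaluates the
        treated count y against p(.|x): swapping the roles changes the
        conditioning and (slightly) the P-value, so callers must keep the
        control library first.  Both orientations still agree with their
        own exact oracle."""
        x, y, n1, n2 = 133, 161, 522584, 349838
        a = two_library_pvalue(CountPair(x=x, y=y, N1=n1, N2=n2))
        b = two_library_pvalue(CountPair(x=y, y=x, N1=n2, N2=n1))
        assert a == pytest.approx(exact_pvalue(x, y, n1, n2), abs=1e-9)
        assert b == pytest.approx(exact_pvalue(y, x, n2, n1), abs=1e-9)
        assert a != b

    def test_monotone_away_from_conditional_expectation(self):
        x, n1, n2 = 100, 10 ** 6, 10 ** 6
        mean = x + 1
        ps_up = [two_library_pvalue(CountPair(x=x, y=y, N1=n1, N2=n2))
                 for y in range(mean, mean + 120, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(ps_up, ps_up[1:]))
        ps_down = [two_library_pvalue(CountPair(x=x, y=y, N1=n1, N2=n2))
                   for y in range(mean, 0, -10)]
        assert all(a >= b - 1e-12 for a, b in zip(ps_down, ps_down[1:]))

    def test_large_counts_stay_finite(self):
        p = two_library_pvalue(CountPair(x=500_000, y=200_000,
                                         N1=5 * 10 ** 6, N2=5 * 10 ** 6))
        assert 0.0 <= p <= 1.0 and math.isfinite(p)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CountPair(x=-1, y=0, N1=10, N2=10)
        with pytest.raises(ValueError):
            CountPair(x=11, y=0, N1=10, N2=10)


def row(entity, fold, p, excluded=False):
    return ExpressionRow(entity_id=entity, kind="miRNA", counts=None,
                         norm_control=1.0, norm_treated=fold,
                         excluded=excluded, fold=fold, p_value=p)


class TestCalls:
    def test_printed_up_example(self):
        (r,) = call_dem([row("gga-miR-29b", 49.0 / 31.5, 4.71e-4)])
        assert r.call == "up"

    def test_threshold_is_strict(self):
        (r,) = call_dem([row("x", 1.5, 0.001)])
        assert r.call == "ns"

    def test_printed_down_example(self):
        (r,) = call_dem([row("gga-miR-1724", 0.004, 0.023)])
        assert r.call == "down"

    def test_p_gate(self):
        (r,) = call_deg([row("x", 2.0, 0.2)])
        assert r.call == "ns"

    def test_deg_table_examples(self):
        (star,) = call_deg([row("STAR", 5.01 / 27.75, 1.28e-8)])
        (cish,) = call_deg([row("CISH", 27.94 / 1.97, 1.38e-10)])
        assert star.call == "down" and cish.call == "up"

    def test_excluded_rows_keep_empty_call(self):
        (r,) = call_dem([row("x", 2.0, 0.001, excluded=True)])
        assert r.call == ""


class TestRankTop:
    def _rows(self):
        df = load_deg_table()
        rows = [row(r.gene, float(r.fold_printed), float(r.p_value))
                for r in df.itertuples()]
        return call_deg(rows)

    def test_top_up_gene_is_rps28(self):
        top = rank_top(self._rows(), 10, "up")
        assert top[0].entity_id == "RPS28"

    def test_k_zero_empty(self):
        assert rank_top(self._rows(), 0, "up") == []

    def test_order_independent_of_input_order(self):
        rows = self._rows()
        a = [r.entity_id for r in rank_top(rows, 10, "down")]
        b = [r.entity_id for r in rank_top(rows[::-1], 10, "down")]
        assert a == b

    def test_k_beyond_available_returns_all(self):
        assert len(rank_top(self._rows(), 99, "up")) == 10


class TestBuildRows:
    def test_normalizes_and_calls(self):
        table = pd.DataFrame({"c": [100, 0, 5], "t": [300, 50, 4]},
                             index=["a", "b", "c"])
        rows = call_dem(build_rows(table, (10 ** 5, 10 ** 5)))
        frame = rows_to_frame(rows)
        assert frame.loc["a", "norm_control"] == pytest.approx(1000.0)
        assert frame.loc["a", "call"] == "up"
        assert frame.loc["b", "norm_control"] == 0.01   # zero revised
        assert frame.loc["b", "call"] == "up"

    def test_gene_rows_need_lengths(self):
        table = pd.DataFrame({"c": [1], "t": [2]}, index=["g"])
        with pytest.raises(ValueError):
            build_rows(table, (10, 10), kind="gene")


def test_dem_table_direction_matches_printed_calls():
    """Applying the decision rule to every printed DEM row (fold from the
    revised printed pair where consistent, else the printed fold) recovers
    the printed up/down direction."""
    df = load_dem_table()
    for r in df.itertuples():
        pair, excluded = revise_and_filter(r.rpm_control, r.rpm_treated)
        assert not excluded
        f = fold_change(pair) if r.fold_consistent else float(r.fold_printed)
        (res,) = call_dem([row(r.mirna, f, float(r.p_value))])
        assert res.call == r.direction, r.mirna
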