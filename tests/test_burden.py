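"""Exact 2x2 statistics, cohort arithmetic and the de novo screens."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from snrnascan.burden import (
    CohortCounts,
    ContingencyTable,
    allele_balance,
    allele_frequency,
    carrier_fraction,
    extrapolated_prevalence,
    fisher_exact,
    recurrent_dnv_screen,
    snrna_burden_screen,
)

from oracles import oracle_conditional_mle, oracle_fisher_p


def test_symmetric_table_is_null():
    res = fisher_exact(((1, 1), (1, 1)))
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_zero_cells_give_boundary_estimates():
    res = fisher_exact(((0, 10), (5, 5)))
    assert res.odds_ratio == 0.0
    assert res.ci_low == 0.0
    res = fisher_exact(((5, 5), (0, 10)))
    assert math.isinf(res.odds_ratio)
    assert math.isinf(res.ci_high)
    with pytest.raises(ValueError, match="all-zero"):
        ContingencyTable(0, 0, 0, 0)


def test_matches_bruteforce_oracle_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(150):
        a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
        if a + b == 0 or c + d == 0:
            continue
        res = fisher_exact(((a, b), (c, d)), compute_ci=False, tol=1e-12)
        assert res.p_value == pytest.approx(oracle_fisher_p(a, b, c, d), rel=1e-9, abs=1e-12)
        expected = oracle_conditional_mle(a, b, c, d)
        if math.isnan(expected):
            assert math.isnan(res.odds_ratio)
        elif math.isinf(expected):
            assert math.isinf(res.odds_ratio)
        else:
            assert res.odds_ratio == pytest.approx(expected, rel=1e-4, abs=1e-10)


def test_matches_scipy_cross_check():
    rng = np.random.default_rng(23)
    for _ in range(40):
        a, b, c, d = (int(x) + 1 for x in rng.integers(0, 40, size=4))
        table = [[a, b], [c, d]]
        ours = fisher_exact(table, tol=1e-12)
        assert ours.p_value == pytest.approx(scipy_fisher(table)[1], rel=1e-9)
        ref = scipy_odds_ratio(table, kind="conditional")
        assert ours.odds_ratio == pytest.approx(ref.statistic, rel=1e-4)


def test_row_swap_antisymmetry():
    rng = np.random.default_rng(31)
    for _ in range(25):
        a, b, c, d = (int(x) + 1 for x in rng.integers(0, 30, size=4))
        res = fisher_exact(((a, b), (c, d)), tol=1e-12)
        swapped = fisher_exact(((c, d), (a, b)), tol=1e-12)
        assert res.odds_ratio * swapped.odds_ratio == pytest.approx(1.0, rel=1e-6)
        assert res.ci_low * swapped.ci_high == pytest.approx(1.0, rel=1e-6)
        assert res.ci_high * swapped.ci_low == pytest.approx(1.0, rel=1e-6)


def test_p_value_invariant_under_transposition():
    rng = np.random.default_rng(37)
    for _ in range(25):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        p1 = fisher_exact(((a, b), (c, d)), compute_ci=False).p_value
        p2 = fisher_exact(((a, c), (b, d)), compute_ci=False).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)


def test_conditional_mle_approaches_cross_product_for_large_cells():
    base = ContingencyTable(2, 3, 4, 5)
    scaled = ContingencyTable(2 * 60, 3 * 60, 4 * 60, 5 * 60)  # min cell 120
    res = fisher_exact(scaled, compute_ci=False, tol=1e-12)
    assert abs(res.odds_ratio - scaled.cross_product_ratio) / scaled.cross_product_ratio < 0.01


def test_one_sided_alternatives_sum_correctly():
    table = ((7, 3), (2, 8))
    less = fisher_exact(table, alternative="less").p_value
    greater = fisher_exact(table, alternative="greater").p_value
    # tails overlap exactly in the observed table's probability
    from oracles import _support_and_weights

    lo, hi, xs, w = _support_and_weights(7, 3, 2, 8)
    obs = w[7 - lo] / sum(w)
    assert less + greater == pytest.approx(1 + obs)


# ---------------------------------------------------------------------------
# cohort arithmetic
# ---------------------------------------------------------------------------

def test_carrier_fraction_examples():
    assert round(carrier_fraction(46, 8841), 2) == 0.52
    assert round(carrier_fraction(92, 119), 1) == 77.3
    assert carrier_fraction(0, 100) == 0.0
    assert round(carrier_fraction(3, 7149), 3) == 0.042
    assert carrier_fraction(CohortCounts(46, 8841, "undiagnosed")) == pytest.approx(0.5203, abs=1e-4)
    with pytest.raises(ValueError):
        carrier_fraction(1, 0)


def test_extrapolated_prevalence_examples():
    assert round(extrapolated_prevalence(60, 8841, 0.4), 2) == 0.41
    assert round(extrapolated_prevalence(60, 8841, 0.0), 2) == 0.68
    assert extrapolated_prevalence(0, 8841, 0.4) == 0.0
    with pytest.raises(ValueError):
        extrapolated_prevalence(60, 8841, 1.0)


def test_allele_frequency_examples():
    assert allele_frequency(1, 490_640) == pytest.approx(1.02e-6, rel=0.01)
    assert allele_frequency(0, 1000) == 0.0
    assert allele_frequency(2000, 1000) == 1.0
    with pytest.raises(ValueError):
        allele_frequency(2001, 1000)


def test_allele_balance_examples():
    assert allele_balance(23, 18) == pytest.approx(0.439, abs=1e-3)
    assert round(100 * allele_balance(23, 18)) == 44
    assert allele_balance(10, 0) == 0.0
    assert allele_balance(5, 5) == 0.5
    with pytest.raises(ValueError):
        allele_balance(0, 0)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def test_burden_screen_bonferroni_alpha():
    counts = {f"g{i}": (2, 0) for i in range(16)}
    screen = snrna_burden_screen(counts, 1000, 1000)
    assert screen.n_tests == 16
    assert screen.alpha_bonferroni == pytest.approx(0.05 / 16)
    assert round(screen.alpha_bonferroni, 4) == 0.0031

    single = snrna_burden_screen({"g": (3, 0)}, 1000, 1000)
    assert single.alpha_bonferroni == pytest.approx(0.05)


def test_burden_screen_inclusion_and_oracle():
    counts = {"u1": (5, 0), "u2": (1, 1), "u3": (2, 2)}
    screen = snrna_burden_screen(counts, 1000, 1000)
    assert screen.n_tests == 2
    assert set(screen.results["unit"]) == {"u1", "u3"}
    for row in screen.results.itertuples(index=False):
        case, ctrl = int(row.case_carriers), int(row.control_carriers)
        expected = oracle_fisher_p(case, 1000 - case, ctrl, 1000 - ctrl)
        assert row.p_value == pytest.approx(expected, rel=1e-9)


def test_burden_screen_empty():
    screen = snrna_burden_screen({"g": (1, 0)}, 100, 100, min_case_dnvs=2)
    assert screen.n_tests == 0
    assert len(screen.results) == 0
    assert math.isnan(screen.alpha_bonferroni)


def test_recurrent_dnv_screen_rules():
    key_ok = ("chr1", 100, "C", "T")
    key_common = ("chr1", 200, "A", "G")
    key_low = ("chr1", 300, "G", "A")
    result = recurrent_dnv_screen(
        {key_ok: 3, key_common: 3, key_low: 2},
        {"diagnosed": {}, "non_ndd": {}},
        {key_common: 0.006},
        min_ac=3,
        max_pop_af=0.005,
    )
    by_variant = {row.variant: row for row in result.itertuples(index=False)}
    assert by_variant["chr1:100:C:T"].retained
    assert not by_variant["chr1:200:A:G"].retained          # population AF 0.6% > 0.5%
    assert "chr1:300:G:A" not in by_variant                 # below min_ac, not a candidate


def test_recurrent_dnv_screen_other_cohort_exclusion():
    key = ("chr1", 100, "C", "T")
    result = recurrent_dnv_screen({key: 4}, {"non_ndd": {key: 1}}, {}, min_ac=3)
    assert not result.iloc[0]["retained"]
    assert not result.iloc[0]["absent_other_cohorts"]
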