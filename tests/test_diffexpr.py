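"""Exact tag-count test: rational-arithmetic oracle, invariants, DE calling."""

from fractions import Fraction
import math

import numpy as np
import pytest
from scipy import stats as sps

from srnamir import diffexpr, simulate
from srnamir.diffexpr import ac_pmf, ac_pvalue, call_de, expression_table, log2_fold_change, normalize


def exact_pmf(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Eq-form pmf in exact rational arithmetic."""
    r = Fraction(n2, n1)
    return r**y * Fraction(math.comb(x + y, y)) / (1 + r) ** (x + y + 1)


def exact_tails(x: int, y: int, n1: int, n2: int) -> tuple[Fraction, Fraction]:
    """C = sum_{k<=y} P(k|x), D = 1 - sum_{k<y} P(k|x), exactly."""
    r = Fraction(n2, n1)
    term = Fraction(1, 1) / (1 + r) ** (x + 1)   # P(0|x)
    c = term
    below = Fraction(0)
    for k in range(y):
        below += term
        term = term * r / (1 + r) * Fraction(x + k + 1, k + 1)
        c += term
    return c, 1 - below


def test_normalize_definition_and_errors():
    assert normalize(0, 10) == 0.0
    assert normalize(10, 10) == 1e6
    assert normalize(100, 10**6) == 100.0
    with pytest.raises(ValueError):
        normalize(1, 0)
    with pytest.raises(ValueError):
        normalize(-1, 10)


def test_log2_fold_change_trivials_and_antisymmetry():
    assert log2_fold_change(5.0, 5.0) == 0.0
    assert log2_fold_change(4.0, 1.0) == 2.0
    assert log2_fold_change(1.0, 4.0) == -log2_fold_change(4.0, 1.0)
    assert log2_fold_change(0.0, 0.0) == 0.0  # both-zero convention


def test_pmf_hand_values():
    assert ac_pmf(0, 0, 10**6, 10**6) == pytest.approx(0.5, rel=1e-12)
    assert ac_pmf(1, 1, 10**6, 10**6) == pytest.approx(0.25, rel=1e-12)
    target = exact_pmf(5, 10, 1_000_000, 2_000_000)
    assert ac_pmf(5, 10, 1_000_000, 2_000_000) == pytest.approx(float(target), rel=1e-12)


def test_pmf_equals_halved_binomial_for_equal_totals():
    for x, y in [(0, 3), (4, 4), (10, 2), (30, 50)]:
        expected = sps.binom.pmf(y, x + y, 0.5) / 2
        assert ac_pmf(x, y, 5_000_000, 5_000_000) == pytest.approx(expected, rel=1e-10)


def test_pvalue_boundary_and_symmetry():
    c, d, p = ac_pvalue(7, 0, 10**6, 10**6)
    assert d == 1.0
    assert c == pytest.approx(ac_pmf(7, 0, 10**6, 10**6), rel=1e-12)
    c, d, p = ac_pvalue(12, 12, 10**6, 10**6)
    assert c + d == pytest.approx(1 + ac_pmf(12, 12, 10**6, 10**6), abs=1e-10)
    assert p == pytest.approx(1.0, abs=1e-9)  # x = y with equal totals is maximally unsurprising


def test_pvalue_against_rational_oracle():
    cases = [(50, 5, 10**6, 10**6), (5, 50, 10**6, 10**6), (20, 35, 10**6, 2 * 10**6), (0, 0, 3, 7)]
    for x, y, n1, n2 in cases:
        ce, de = exact_tails(x, y, n1, n2)
        pe = min(1, 2 * min(ce, de))
        c, d, p = ac_pvalue(x, y, n1, n2)
        assert c == pytest.approx(float(ce), rel=1e-9, abs=1e-12)
        assert d == pytest.approx(float(de), rel=1e-9, abs=1e-12)
        assert p == pytest.approx(float(pe), rel=1e-9, abs=1e-12)


def test_oracle_equivalence_small_grid():
    """Float implementation tracks exact rationals on a dense small grid."""
    for n1, n2 in [(10**6, 5 * 10**5), (10**6, 10**6), (10**6, 2 * 10**6)]:
        for x in range(0, 41, 8):
            for y in range(0, 41, 8):
                ce, de = exact_tails(x, y, n1, n2)
                c, d, _ = ac_pvalue(x, y, n1, n2)
                assert c == pytest.approx(float(ce), rel=1e-9, abs=1e-12)
                assert d == pytest.approx(float(de), rel=1e-9, abs=1e-12)


def test_pmf_mass_sums_to_one():
    for ratio in (0.5, 1.0, 2.0):
        n1, n2 = 10**6, int(ratio * 10**6)
        for x in (0, 1, 5, 50):
            ks = np.arange(0, 3000)
            total = sum(ac_pmf(x, int(k), n1, n2) for k in ks)
            assert total == pytest.approx(1.0, abs=1e-9)


def test_pvalue_monotone_along_tails():
    n1 = n2 = 10**6
    x = 30
    ps = [ac_pvalue(x, y, n1, n2)[2] for y in range(0, 100)]
    mode = int(np.argmax(ps))
    assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(mode, 99))
    assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(0, mode))


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        ac_pmf(-1, 0, 10, 10)
    with pytest.raises(ValueError):
        ac_pvalue(0, 0, 0, 10)


def test_call_de_gates():
    df = expression_table(
        [("a", 40, 100), ("b", 10, 100)], total_treated=10**6, total_control=10**6
    )
    df.loc[0, ["p_value", "log2fc"]] = [0.04, 0.8]     # fold-change gate fails
    df.loc[1, ["p_value", "log2fc"]] = [0.005, -1.5]   # DE, significant, down
    flagged, tallies = call_de(df)
    assert not flagged.loc[0, "de"]
    assert flagged.loc[1, "de"] and flagged.loc[1, "sig"] and flagged.loc[1, "direction"] == "down"
    assert tallies == {"n_de": 1, "n_up": 0, "n_down": 1, "n_sig": 1, "n_sig_up": 0, "n_sig_down": 1}


def test_null_fixture_type_one_error_controlled():
    """With no true DE, the flagged fraction stays below 7% over seeds."""
    flagged = total = 0
    for seed in range(10):
        df = simulate.draw_library_counts(200, de_fraction=0.0, seed=seed)
        totals = df.attrs["totals"]
        expr = expression_table(
            df[["mirna_id", "count_treated", "count_control"]],
            total_treated=totals["treated"],
            total_control=totals["control"],
        )
        out, tallies = call_de(expr)
        flagged += tallies["n_de"]
        total += len(out)
    assert flagged / total <= 0.07


def test_planted_two_fold_log2_changes_are_detected():
    """|lfc| = 2 with expected counts >= 50 is flagged nearly always."""
    hit = n_de = 0
    for seed in range(10):
        df = simulate.draw_library_counts(
            100, de_fraction=0.2, true_lfc_values=(-2.0, 2.0), seed=seed
        )
        totals = df.attrs["totals"]
        expr = expression_table(
            df[["mirna_id", "count_treated", "count_control"]],
            total_treated=totals["treated"],
            total_control=totals["control"],
        )
        out, _ = call_de(expr)
        truth_de = df["true_lfc"].abs() >= 1
        hit += int((out["de"] & truth_de).sum())
        n_de += int(truth_de.sum())
    assert hit / n_de >= 0.9


def test_swap_totals_binding():
    a = expression_table([("m", 10, 30)], 10**6, 2 * 10**6)
    b = expression_table([("m", 10, 30)], 10**6, 2 * 10**6, swap_totals=True)
    assert a.loc[0, "N1"] == 10**6 and b.loc[0, "N1"] == 2 * 10**6
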