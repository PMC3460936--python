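"""Pearson/Spearman estimates, Fisher-z intervals and exact permutation p."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regionrisk import (
    FactorSpec,
    RegionRecord,
    RegionTable,
    grouped_correlations,
    pearson_with_ci,
    spearman,
)
from regionrisk.correlation import DegenerateInputError

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def direct_pearson(x, y):
    """Textbook covariance / (σx σy), written from the definition."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def midrank(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_spearman_p(x, y):
    """Exact two-sided permutation p over all n! pairings of mid-ranks."""
    rx, ry = midrank(x), midrank(y)
    obs = abs(direct_pearson(rx, ry))
    count = total = 0
    for perm in permutations(ry):
        if abs(direct_pearson(rx, list(perm))) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def test_perfect_linearity_gives_one():
    res = pearson_with_ci([1, 2, 3, 4, 5], [3, 5, 7, 9, 11])
    assert res.estimate == 1.0
    assert res.p_value == 0.0
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)


def test_pearson_matches_direct_formula_oracle():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.0, 1.0, 4.0, 3.0, 5.0]
    res = pearson_with_ci(x, y)
    assert res.estimate == pytest.approx(direct_pearson(x, y), abs=1e-14)


def test_pearson_matches_scipy_cross_check():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=30), rng.normal(size=30)
    res = pearson_with_ci(x, y)
    ref = stats.pearsonr(x, y)
    assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
    lo, hi = ref.confidence_interval(0.95)
    assert res.ci_low == pytest.approx(lo, abs=1e-9)
    assert res.ci_high == pytest.approx(hi, abs=1e-9)


def test_n_three_interval_is_full_range():
    res = pearson_with_ci([1, 2, 4], [2, 5, 6])
    assert (res.ci_low, res.ci_high) == (-1.0, 1.0)
    assert -1 < res.estimate < 1


def test_zero_variance_is_degenerate():
    with pytest.raises(DegenerateInputError):
        pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(-100, 100).map(float), min_size=4, max_size=20, unique=True),
    st.floats(0.1, 10),
    st.floats(-50, 50),
)
def test_pearson_affine_invariance_and_sign_flip(x, scale, shift):
    rng = np.random.default_rng(abs(hash(tuple(x))) % 2**31)
    y = list(rng.normal(size=len(x)))
    if np.std(y) == 0:
        return
    base = pearson_with_ci(x, y).estimate
    scaled = pearson_with_ci([scale * v + shift for v in x], y).estimate
    flipped = pearson_with_ci([-v for v in x], y).estimate
    assert scaled == pytest.approx(base, abs=1e-9)
    assert flipped == pytest.approx(-base, abs=1e-9)


def test_correlation_symmetry():
    rng = np.random.default_rng(9)
    x, y = rng.normal(size=12), rng.normal(size=12)
    assert pearson_with_ci(x, y).estimate == pytest.approx(
        pearson_with_ci(y, x).estimate, abs=1e-15
    )
    assert spearman(x, y).estimate == pytest.approx(
        spearman(y, x).estimate, abs=1e-15
    )


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_monotone_transform_gives_one():
    x = [1.0, 2.5, 3.0, 7.0, 11.0]
    y = [math.exp(v / 3) for v in x]
    assert spearman(x, y).estimate == 1.0


def test_reversal_gives_minus_one():
    res = spearman([1, 2, 3, 4], [4, 3, 2, 1])
    assert res.estimate == -1.0
    # only the two perfectly monotone pairings among 4! are this extreme
    assert res.p_value == pytest.approx(2 / 24)


def test_spearman_exact_p_matches_enumeration_n7():
    rng = np.random.default_rng(13)
    x = list(rng.normal(size=7))
    y = list(rng.normal(size=7))
    res = spearman(x, y)
    assert res.p_value == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)


def test_spearman_exact_p_with_ties_matches_enumeration():
    x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
    y = [2.0, 3.0, 1.0, 4.0, 4.0, 5.0]
    res = spearman(x, y)
    assert res.p_value == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)


def test_spearman_estimate_matches_scipy_with_ties():
    x = [1.0, 1.0, 2.0, 5.0, 5.0, 5.0, 9.0, 10.0, 11.0, 11.0]
    y = [3.0, 4.0, 4.0, 1.0, 7.0, 8.0, 8.0, 2.0, 9.0, 9.0]
    res = spearman(x, y)
    ref = stats.spearmanr(x, y)
    assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)  # n=10 → t approx


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(-100, 100).map(float), min_size=4, max_size=7, unique=True))
def test_spearman_invariant_under_monotone_transform(x):
    rng = np.random.default_rng(abs(hash(tuple(x))) % 2**31)
    y = list(rng.normal(size=len(x)))
    base = spearman(x, y)
    warped = spearman([math.atan(v / 10) for v in x], y)  # strictly monotone
    assert warped.estimate == pytest.approx(base.estimate, abs=1e-12)
    assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)


# ---------------------------------------------------------------------------
# Grouped correlations
# ---------------------------------------------------------------------------

def _grouped_table():
    factors = [FactorSpec("mortality_rate", "direct", 2, "per 100k"),
               FactorSpec("uninsured_pct", "direct", 1, "%")]
    records = []
    # group A: y = x exactly (5 regions)
    for i in range(5):
        records.append(RegionRecord(f"A{i}", group_id="A", values={
            "mortality_rate": 20.0 + i, "uninsured_pct": 5.0 + i}))
    # group B: fixed irregular pattern (4 regions)
    bx = [22.0, 25.0, 21.0, 28.0]
    by = [9.0, 6.0, 8.0, 12.0]
    for i in range(4):
        records.append(RegionRecord(f"B{i}", group_id="B", values={
            "mortality_rate": bx[i], "uninsured_pct": by[i]}))
    # group C: too small to report
    for i in range(2):
        records.append(RegionRecord(f"C{i}", group_id="C", values={
            "mortality_rate": 24.0 + i, "uninsured_pct": 7.0 + i}))
    return RegionTable(records, factors), bx, by


def test_grouped_correlations_per_group_and_pooled():
    table, bx, by = _grouped_table()
    results, skipped = grouped_correlations(
        table, [("mortality_rate", "uninsured_pct")]
    )
    by_key = {(r.group_id, r.method): r for r in results}
    assert by_key[("A", "pearson")].estimate == pytest.approx(1.0)
    assert by_key[("B", "pearson")].estimate == pytest.approx(
        direct_pearson(bx, by), abs=1e-12
    )
    pooled = by_key[(None, "pearson")]
    assert pooled.n == 11  # the 2-region group still contributes to pooled
    assert [(s.group_id, s.reason) for s in skipped] == [("C", "n < 3")]


def test_grouped_correlations_unknown_factor_errors():
    table, _, _ = _grouped_table()
    with pytest.raises(Exception, match="nope"):
        grouped_correlations(table, [("mortality_rate", "nope")])


def test_fisher_ci_widens_at_small_n():
    rng = np.random.default_rng(21)
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    wide = pearson_with_ci(x[:5], y[:5])
    narrow = pearson_with_ci(x, y)
    assert (wide.ci_high - wide.ci_low) > (narrow.ci_high - narrow.ci_low)
    assert narrow.ci_low <= narrow.estimate <= narrow.ci_high
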