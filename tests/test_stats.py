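"""Statistical kernel: worked examples, oracles, and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from mtoraxis import (
    bh_fdr,
    chi2_test,
    cliffs_delta,
    fisher_exact_2x2,
    linear_model_robust,
    mann_whitney,
    select_2x2_test,
)


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p, expected", [
    ([0.03], [0.03]),
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.5, 0.1], [0.5, 0.2]),
])
def test_bh_step_up_by_hand(p, expected):
    np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(1)
    p = rng.uniform(size=200) ** 2
    ours = bh_fdr(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, theirs, rtol=1e-12)


def test_bh_empty_and_bounds():
    assert bh_fdr([]).size == 0
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_properties(p):
    q = bh_fdr(p)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1)
    perm = np.random.default_rng(0).permutation(len(p))
    np.testing.assert_allclose(bh_fdr(np.asarray(p)[perm]), q[perm], rtol=1e-12)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def enumeration_fisher_p(table):
    """Independent oracle: sum hypergeometric mass over fixed-margin tables."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = hypergeom.pmf(x, n, c1, r1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


@pytest.mark.parametrize("table, p, or_", [
    ([[10, 10], [10, 10]], 1.0, 1.0),
    ([[5, 0], [0, 5]], 2 / 252, 121.0),   # Haldane-corrected OR
    ([[3, 1], [1, 3]], None, 9.0),
])
def test_fisher_worked_examples(table, p, or_):
    res = fisher_exact_2x2(table)
    if p is not None:
        assert res.p_value == pytest.approx(p, rel=1e-9)
    assert res.effect == pytest.approx(or_, rel=1e-9)


def test_fisher_zero_cell_flags_haldane_not_p():
    res = fisher_exact_2x2([[5, 0], [0, 5]])
    assert res.haldane_corrected
    # exact p is computed on raw counts: equals the enumeration oracle
    assert res.p_value == pytest.approx(enumeration_fisher_p([[5, 0], [0, 5]]))


def test_fisher_degenerate_margin_non_evaluable():
    res = fisher_exact_2x2([[0, 0], [3, 4]])
    assert not res.evaluable and res.p_value == 1.0 and res.effect is None


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(100):
        t = rng.integers(0, 16, size=(2, 2))
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            continue
        res = fisher_exact_2x2(t)
        assert res.p_value == pytest.approx(enumeration_fisher_p(t), rel=1e-8)


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

def test_chi2_identical_rows_is_null():
    res = chi2_test([[20, 30], [20, 30]], yates=False)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_hand_computed_pearson():
    res = chi2_test([[20, 80], [40, 60]], yates=False)
    assert res.statistic == pytest.approx(200 / 21, rel=1e-12)  # 9.5238...


def test_chi2_yates_shrinks_statistic():
    pearson = chi2_test([[20, 80], [40, 60]], yates=False).statistic
    yates = chi2_test([[20, 80], [40, 60]], yates=True).statistic
    assert yates < pearson


def test_chi2_yates_rejected_on_kx2():
    with pytest.raises(ValueError):
        chi2_test([[5, 5], [5, 5], [5, 5]], yates=True)


def test_select_rule_uses_fisher_on_sparse_and_yates_otherwise():
    assert select_2x2_test([[2, 3], [4, 1]]).test_name == "fisher_exact"
    assert select_2x2_test([[20, 80], [40, 60]]).test_name == "chi2_yates"


# ---------------------------------------------------------------------------
# Mann-Whitney and Cliff's delta
# ---------------------------------------------------------------------------

def test_mwu_exact_small_sample():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.p_value == pytest.approx(0.1)
    assert res.statistic in (0.0, 9.0)


def test_mwu_identical_multisets_p_one():
    res = mann_whitney([1.5, 2.5, 3.5], [1.5, 2.5, 3.5])
    assert res.p_value == pytest.approx(1.0)


def test_mwu_planted_shift_power(rng):
    g0 = rng.standard_normal(200)
    g1 = rng.standard_normal(200) + 1.0
    assert mann_whitney(g0, g1).p_value < 1e-10


def test_mwu_requires_nonempty():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


@pytest.mark.parametrize("g0, g1, expected", [
    ([1, 2, 3], [1, 2, 3], 0.0),
    ([1, 2], [5, 6], 1.0),
    ([1, 2], [2, 3], 0.75),
])
def test_cliffs_delta_examples(g0, g1, expected):
    assert cliffs_delta(g0, g1) == pytest.approx(expected)


def test_cliffs_delta_matches_cross_pair_oracle(rng):
    for _ in range(20):
        g0 = rng.integers(0, 10, size=rng.integers(2, 15)).astype(float)
        g1 = rng.integers(0, 10, size=rng.integers(2, 15)).astype(float)
        brute = np.mean([np.sign(b - a) for a, b in itertools.product(g0, g1)])
        assert cliffs_delta(g0, g1) == pytest.approx(brute)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(-50, 50), min_size=1, max_size=20),
    st.lists(st.floats(-50, 50), min_size=1, max_size=20),
)
def test_cliffs_delta_antisymmetric(g0, g1):
    assert cliffs_delta(g0, g1) == pytest.approx(-cliffs_delta(g1, g0))
    assert -1 <= cliffs_delta(g0, g1) <= 1


def test_cliffs_delta_extreme_iff_separation():
    assert cliffs_delta([1, 2], [3, 4]) == 1.0
    assert abs(cliffs_delta([1, 3], [2, 4])) < 1.0  # interleaved


# ---------------------------------------------------------------------------
# Robust linear model
# ---------------------------------------------------------------------------

def test_ols_recovers_exact_indicator():
    import pandas as pd
    genotype = np.array([0, 0, 1, 1, 0, 1, 0, 1], dtype=float)
    design = pd.DataFrame({"genotype": genotype})
    coefs = linear_model_robust(genotype, design, cohort_col=None)
    assert coefs.loc["genotype", "estimate"] == pytest.approx(1.0)


def test_ols_null_coverage(rng):
    import pandas as pd
    cover = 0
    reps = 100
    for _ in range(reps):
        y = rng.standard_normal(120)
        design = pd.DataFrame({
            "genotype": rng.integers(0, 2, 120).astype(float),
            "cohort": rng.choice(["a", "b", "c"], 120),
        })
        c = linear_model_robust(y, design)
        cover += c.loc["genotype", "ci_lo"] <= 0 <= c.loc["genotype", "ci_hi"]
    assert cover >= 0.90 * reps


def test_ols_rank_deficiency_named():
    import pandas as pd
    design = pd.DataFrame({"genotype": [1.0, 1.0, 1.0, 1.0]})
    with pytest.raises(ValueError, match="rank"):
        linear_model_robust(np.zeros(4), design, cohort_col=None)


def test_mwu_type_I_error_calibrated(rng):
    hits = 0
    reps = 1000
    for _ in range(reps):
        if mann_whitney(rng.standard_normal(50), rng.standard_normal(50)).p_value < 0.05:
            hits += 1
    assert 0.03 < hits / reps < 0.07
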