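"""Statistical kernel shared by every pipeline stage.

Provides Benjamini-Hochberg FDR control, 2x2 and Kx2 contingency tests with
the sparse-count selection rule used throughout the pipeline (Fisher's exact
test when any expected count is below 5, otherwise a Yates-corrected chi-square
for 2x2 tables and plain Pearson for Kx2 heterogeneity tables), the
Mann-Whitney U test with Cliff's delta effect size, and OLS with
heteroskedasticity-consistent (HC1) standard errors for covariate-adjusted
group contrasts.

All routines are pure and operate on in-memory arrays; results are returned
as small dataclasses that serialize cleanly into the downstream TSV/JSON
schemas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bh_fdr",
    "fisher_exact_2x2",
    "chi2_test",
    "select_2x2_test",
    "mann_whitney",
    "cliffs_delta",
    "linear_model_robust",
]

EXPECTED_COUNT_RULE = 5.0  # Fisher below this minimum expected cell count


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``test_name`` records which rule fired (``fisher_exact``, ``chi2_yates``,
    ``chi2_pearson`` or ``mann_whitney``).  ``effect`` carries the odds ratio
    for contingency tests and Cliff's delta for rank tests.  ``evaluable`` is
    False when a degenerate margin made the test undefined, in which case
    ``p_value`` is 1 and the effect is missing.
    """

    statistic: float
    p_value: float
    test_name: str
    effect: Optional[float] = None
    n_evaluable: int = 0
    evaluable: bool = True
    haldane_corrected: bool = False
    effect_ci: Optional[tuple[float, float]] = None
    expected: Optional[np.ndarray] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    Ties and zeros are allowed; an empty input yields an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------

def _as_2x2(table: Sequence[Sequence[float]]) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("expected a 2x2 table of non-negative integers")
    return t


def _odds_ratio(t: np.ndarray) -> tuple[float, bool, tuple[float, float]]:
    """Point OR with Haldane-Anscombe +0.5 on all cells when any cell is 0.

    The continuity correction applies to the estimate and its Wald CI only;
    exact p-values are always computed on the raw counts.  Returns
    (or, corrected_flag, (ci_lo, ci_hi)) with a normal-approximation 95% CI
    on the log odds ratio.
    """
    corrected = bool(np.any(t == 0))
    tc = t + 0.5 if corrected else t
    a, b, c, d = tc.ravel()
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.log(or_) - 1.959963984540054 * se
    hi = math.log(or_) + 1.959963984540054 * se
    return or_, corrected, (math.exp(lo), math.exp(hi))


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Two-sided Fisher's exact test with odds ratio.

    The two-sided p sums hypergeometric probabilities of all fixed-margin
    tables whose probability does not exceed the observed table's
    (probability-mass method).  A row or column summing to zero makes the
    test undefined: the result is flagged non-evaluable with p = 1.
    """
    t = _as_2x2(table)
    n = int(t.sum())
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return TestResult(np.nan, 1.0, "fisher_exact", None, n, evaluable=False)
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    or_, corrected, ci = _odds_ratio(t)
    return TestResult(
        statistic=or_, p_value=float(p), test_name="fisher_exact",
        effect=or_, n_evaluable=n, haldane_corrected=corrected, effect_ci=ci,
    )


def chi2_test(table: Sequence[Sequence[float]], yates: bool = True) -> TestResult:
    """Chi-square test on a 2x2 (optionally Yates-corrected) or Kx2 (Pearson) table.

    Yates' continuity correction is defined for 2x2 tables only; requesting it
    on a Kx2 table raises.  The expected-count matrix is attached to the
    result for the caller's selection rule.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2 or np.any(t < 0):
        raise ValueError("expected a Kx2 table (K >= 2) of non-negative counts")
    if yates and t.shape != (2, 2):
        raise ValueError("Yates correction is defined for 2x2 tables only")
    name = "chi2_yates" if yates else "chi2_pearson"
    n = int(t.sum())
    # identical-rows / degenerate margins: statistic 0 by convention
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return TestResult(np.nan, 1.0, name, None, n, evaluable=False)
    stat, p, _, expected = sps.chi2_contingency(t, correction=yates)
    effect = None
    if t.shape == (2, 2):
        effect = _odds_ratio(t)[0]
    return TestResult(float(stat), float(p), name, effect, n, expected=expected)


def select_2x2_test(table: Sequence[Sequence[float]]) -> TestResult:
    """Sparse-count selection rule for 2x2 tables.

    Fisher's exact test when any expected count is below 5, otherwise the
    Yates-corrected chi-square.  Degenerate margins fall through to Fisher's
    non-evaluable handling.
    """
    t = _as_2x2(table)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    n = t.sum()
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return fisher_exact_2x2(t)
    expected = rows @ cols / n
    if np.any(expected < EXPECTED_COUNT_RULE):
        return fisher_exact_2x2(t)
    res = chi2_test(t, yates=True)
    or_, corrected, ci = _odds_ratio(t)
    res.effect = or_
    res.haldane_corrected = corrected
    res.effect_ci = ci
    return res


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

EXACT_MWU_MAX_N = 20  # exact null enumeration up to this combined sample size


def mann_whitney(group0: Sequence[float], group1: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the permutation null when n0 + n1 <= 20 and the data
    are tie-free; otherwise the tie-corrected, continuity-corrected normal
    approximation.  The reported U counts pairs where group1 exceeds group0
    (U1 convention), recorded alongside Cliff's delta in ``effect``.
    """
    x0 = np.asarray(group0, dtype=float)
    x1 = np.asarray(group1, dtype=float)
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x0, x1])
    exact = (x0.size + x1.size <= EXACT_MWU_MAX_N
             and np.unique(pooled).size == pooled.size)
    res = sps.mannwhitneyu(
        x1, x0, alternative="two-sided",
        method="exact" if exact else "asymptotic", use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        test_name="mann_whitney", effect=cliffs_delta(x0, x1),
        n_evaluable=x0.size + x1.size,
    )


def cliffs_delta(group0: Sequence[float], group1: Sequence[float]) -> float:
    """Cliff's delta: net proportion of cross-pairs where group1 > group0.

    delta = (#{x1 > x0} - #{x1 < x0}) / (n0 * n1), in [-1, 1]; positive means
    group1 is stochastically larger.
    """
    x0 = np.asarray(group0, dtype=float)
    x1 = np.asarray(group1, dtype=float)
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both groups must be non-empty")
    # O((n0+n1) log) via ranks rather than the n0*n1 cross-pair matrix
    wins = 0.0
    order = np.sort(x0)
    hi = np.searchsorted(order, x1, side="left")     # x0 strictly below each x1
    lo = x0.size - np.searchsorted(order, x1, side="right")  # strictly above
    wins = float(np.sum(hi) - np.sum(lo))
    return wins / (x0.size * x1.size)


# ---------------------------------------------------------------------------
# Covariate-adjusted linear model
# ---------------------------------------------------------------------------

def linear_model_robust(
    response: Sequence[float],
    design: pd.DataFrame,
    genotype_col: str = "genotype",
    cohort_col: Optional[str] = "cohort",
) -> pd.DataFrame:
    """OLS with HC1 (sandwich) standard errors and Wald 95% CIs.

    ``design`` holds a binary genotype indicator and, optionally, a
    categorical cohort column that is dummy-encoded against a reference
    level.  Returns a coefficient table indexed by term with columns
    ``estimate``, ``se``, ``ci_lo``, ``ci_hi``, ``p``.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = pd.DataFrame({genotype_col: np.asarray(design[genotype_col], dtype=float)})
    if cohort_col is not None and cohort_col in design.columns:
        dummies = pd.get_dummies(
            design[cohort_col].astype("category"), prefix=cohort_col,
            drop_first=True, dtype=float,
        )
        X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X.reset_index(drop=True), prepend=True, has_constant="add")
    if y.size <= X.shape[1]:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns): "
                         f"check columns {list(X.columns)}")
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "ci_lo": ci[0],
        "ci_hi": ci[1],
        "p": fit.pvalues,
    })
    out.index.name = "term"
    return out
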