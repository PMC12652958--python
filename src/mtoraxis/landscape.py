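"""Pan-cancer alteration landscape: prevalence, specificity, heterogeneity.

For each gene in the panel this stage derives per-cohort alteration
prevalences (percent of evaluable samples altered), summarizes lineage
dispersion with the normalized Shannon entropy H and the tau specificity
index, assigns a Shared / Tumor-specific / Ambiguous class from prespecified
cutoffs, and tests between-cohort heterogeneity with a Kx2 contingency test,
BH-FDR corrected across the panel.

Alteration modes: ``mutation`` counts samples with at least one
non-synonymous call; ``amplification`` counts GISTIC calls in {+1,+2};
``deletion`` counts {-1,-2}; ``union`` counts mutation OR the
role-appropriate copy-number event (amplification for oncogenes, deletion
for tumor suppressors, any non-zero call for unspecified genes).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import CohortAlterationTable, default_role
from .stats import TestResult, bh_fdr, chi2_test, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationCutoffs",
    "PrevalenceMatrix",
    "read_alteration_inputs",
    "compute_prevalence",
    "normalized_entropy",
    "tau_index",
    "classify_gene",
    "heterogeneity_test",
    "landscape_table",
]

NONSYNONYMOUS = {
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
    "Translation_Start_Site", "Nonstop_Mutation",
}


@dataclass
class ClassificationCutoffs:
    """Shared / Tumor-specific decision rule parameters (percent units)."""

    shared_min_pct: float = 5.0
    shared_min_studies: int = 5
    specific_diff_pp: float = 10.0


@dataclass
class PrevalenceMatrix:
    """Genes x cohorts percentages with per-cohort evaluable N."""

    values: pd.DataFrame          # percent altered, [0, 100]
    n_per_cohort: pd.Series       # evaluable samples per cohort
    mode: str

    @property
    def cohorts(self) -> pd.Index:
        return self.values.columns

    def pan_percent(self) -> pd.Series:
        """Pooled-sample pan-cancer percentage (sample-weighted cohort mean)."""
        w = self.n_per_cohort.reindex(self.values.columns).to_numpy(dtype=float)
        return pd.Series(
            (self.values.to_numpy() * w).sum(axis=1) / w.sum(),
            index=self.values.index,
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_alteration_inputs(
    maf_path: Path | str, gistic_path: Path | str, cohorts_path: Path | str,
) -> CohortAlterationTable:
    """Load MAF-like TSV + GISTIC thresholded TSV + cohort map into one table.

    Samples come from the cohort map; mutation flags mark samples with at
    least one non-synonymous variant call for the gene.
    """
    cohorts = pd.read_csv(cohorts_path, sep="\t", index_col=0)["cohort"]
    maf = pd.read_csv(maf_path, sep="\t")
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    if not required <= set(maf.columns):
        raise ValueError(f"MAF-like file must contain columns {sorted(required)}")
    gistic = pd.read_csv(gistic_path, sep="\t", index_col=0)
    genes = gistic.index
    samples = cohorts.index
    unknown = set(maf["Tumor_Sample_Barcode"]) - set(samples)
    if unknown:
        raise ValueError(f"samples missing a cohort assignment: {sorted(unknown)[:5]}")

    mut = pd.DataFrame(False, index=samples, columns=genes)
    keep = maf["Variant_Classification"].isin(NONSYNONYMOUS)
    for _, row in maf.loc[keep].iterrows():
        if row["Hugo_Symbol"] in mut.columns:
            mut.loc[row["Tumor_Sample_Barcode"], row["Hugo_Symbol"]] = True
    cna = gistic.T.reindex(samples).fillna(0).astype(int)
    return CohortAlterationTable(mut, cna, cohorts)


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------

def _altered_matrix(
    alterations: CohortAlterationTable, mode: str, roles: Optional[dict[str, str]],
) -> pd.DataFrame:
    mut, cna = alterations.mutations, alterations.cna
    if mode == "mutation":
        return mut.copy()
    if mode == "amplification":
        return cna > 0
    if mode == "deletion":
        return cna < 0
    if mode == "union":
        out = mut.copy()
        for g in out.columns:
            role = (roles or {}).get(g, default_role(g))
            if role == "oncogene":
                out[g] |= cna[g] > 0
            elif role == "tumor_suppressor":
                out[g] |= cna[g] < 0
            else:
                out[g] |= cna[g] != 0
        return out
    raise ValueError(f"unknown mode {mode!r}")


def compute_prevalence(
    alterations: CohortAlterationTable,
    mode: str = "union",
    roles: Optional[dict[str, str]] = None,
) -> PrevalenceMatrix:
    """Percent of evaluable samples altered, per gene and cohort."""
    altered = _altered_matrix(alterations, mode, roles)
    cohort = alterations.cohort_of.reindex(altered.index)
    if cohort.isna().any():
        raise ValueError("every sample must be assigned to exactly one cohort")
    counts = altered.groupby(cohort, observed=True).sum().T
    n = cohort.value_counts().reindex(counts.columns)
    values = counts / n * 100.0
    return PrevalenceMatrix(values=values, n_per_cohort=n, mode=mode)


# ---------------------------------------------------------------------------
# Specificity metrics
# ---------------------------------------------------------------------------

def normalized_entropy(prevalences: Sequence[float]) -> float:
    """Normalized Shannon entropy of a non-negative prevalence vector.

    H = -sum(p_i log p_i) / log K on the sum-normalized vector, with
    0 log 0 = 0; natural log (the normalization makes the base irrelevant).
    1 = uniform across cohorts, 0 = concentrated in one.  An all-zero
    vector returns 0 (degenerate: no events to spread).
    """
    x = np.asarray(prevalences, dtype=float)
    if x.size < 2:
        raise ValueError("entropy needs at least two cohorts")
    if np.any(x < 0):
        raise ValueError("prevalences must be non-negative")
    total = x.sum()
    if total == 0:
        return 0.0
    p = x / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(x.size))


def tau_index(prevalences: Sequence[float]) -> float:
    """Tau specificity index: sum(1 - x_i/x_max) / (K - 1).

    0 = uniform across cohorts, 1 = restricted to a single cohort.  Returns
    NaN when the vector is all zero (specificity undefined).
    """
    x = np.asarray(prevalences, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least two cohorts")
    if np.any(x < 0):
        raise ValueError("prevalences must be non-negative")
    if x.max() == 0:
        return float("nan")
    return float((1.0 - x / x.max()).sum() / (x.size - 1))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_gene(
    prevalences: pd.Series,
    n_per_cohort: pd.Series,
    cutoffs: ClassificationCutoffs = ClassificationCutoffs(),
) -> tuple[str, str, str, float]:
    """Class label plus top/second cohorts and their prevalence gap.

    Shared (>= shared_min_pct in >= shared_min_studies cohorts) takes
    precedence over Tumor-specific (top - second >= specific_diff_pp), so a
    broadly prevalent gene with one dominant lineage is still Shared.
    Ties on prevalence break toward the larger cohort, then the
    lexicographically smaller label.
    """
    x = prevalences
    order = sorted(
        x.index,
        key=lambda c: (-x[c], -float(n_per_cohort.get(c, 0)), c),
    )
    top, second = order[0], order[1]
    diff = float(x[top] - x[second])
    if len(x) < cutoffs.shared_min_studies:
        warnings.warn(
            f"only {len(x)} cohorts < shared_min_studies={cutoffs.shared_min_studies}; "
            "classifying as Ambiguous")
        return "Ambiguous", top, second, diff
    if int((x >= cutoffs.shared_min_pct).sum()) >= cutoffs.shared_min_studies:
        return "Shared", top, second, diff
    if diff >= cutoffs.specific_diff_pp:
        return "Tumor-specific", top, second, diff
    return "Ambiguous", top, second, diff


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------

def heterogeneity_test(
    altered_counts: Sequence[float], n_per_cohort: Sequence[float],
) -> TestResult:
    """Kx2 between-cohort heterogeneity test for one gene.

    Pearson chi-square on the (altered, not-altered) x cohort table; when any
    expected count drops below 5 the p-value comes from a Monte-Carlo
    exact test (2x2 tables use Fisher directly).  Cohorts with N = 0 are
    dropped with a warning.
    """
    a = np.asarray(altered_counts, dtype=float)
    n = np.asarray(n_per_cohort, dtype=float)
    keep = n > 0
    if not np.all(keep):
        warnings.warn("dropping cohorts with zero evaluable samples")
        a, n = a[keep], n[keep]
    table = np.column_stack([a, n - a])
    if table.shape[0] < 2:
        return TestResult(np.nan, 1.0, "chi2_pearson", None, int(n.sum()), evaluable=False)
    if np.any(table.sum(axis=0) == 0):
        return TestResult(0.0, 1.0, "chi2_pearson", None, int(n.sum()))
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    if np.any(expected < 5):
        if table.shape[0] == 2:
            return fisher_exact_2x2(np.round(table).astype(int))
        return _monte_carlo_chi2(np.round(table).astype(int))
    return chi2_test(table, yates=False)


def _monte_carlo_chi2(table: np.ndarray, n_sim: int = 2000, seed: int = 7) -> TestResult:
    """Monte-Carlo exact p for a Kx2 table under fixed margins."""
    from scipy.stats import chi2_contingency, random_table

    obs_stat = chi2_contingency(table, correction=False)[0]
    rt = random_table(table.sum(axis=1), table.sum(axis=0),
                      seed=np.random.default_rng(seed))
    sims = rt.rvs(n_sim)
    count = 0
    for s in sims:
        stat = chi2_contingency(s + 1e-300, correction=False)[0]
        if stat >= obs_stat - 1e-9:
            count += 1
    p = (1 + count) / (1 + n_sim)
    return TestResult(float(obs_stat), float(p), "chi2_pearson", None,
                      int(table.sum()))


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

LANDSCAPE_COLUMNS = [
    "Gene", "Mutated%_Pan", "Amplified%_Pan", "Entropy", "Tau", "Class",
    "Top_Cancer", "Second_Cancer", "Top_vs_Second_Diff(%)", "Chi2_p", "BH-FDR_q",
]


def landscape_table(
    alterations: CohortAlterationTable,
    roles: Optional[dict[str, str]] = None,
    cutoffs: ClassificationCutoffs = ClassificationCutoffs(),
    genes: Optional[Sequence[str]] = None,
    outdir: Optional[Path | str] = None,
) -> pd.DataFrame:
    """One specificity record per gene, in the published table schema.

    Entropy, tau, classification and heterogeneity all operate on the
    union-mode prevalence vector; pan-level percentages pool every sample.
    """
    genes = list(genes) if genes is not None else list(alterations.genes)
    union = compute_prevalence(alterations, "union", roles)
    mut = compute_prevalence(alterations, "mutation", roles)
    amp = compute_prevalence(alterations, "amplification", roles)
    n = union.n_per_cohort

    mut_pan, amp_pan = mut.pan_percent(), amp.pan_percent()
    rows, pvals = [], []
    for g in genes:
        vec = union.values.loc[g]
        cls, top, second, diff = classify_gene(vec, n, cutoffs)
        # round half away from zero for platform-stable reconstructed counts
        counts = np.floor(vec.to_numpy() * n.to_numpy() / 100.0 + 0.5)
        het = heterogeneity_test(counts, n.to_numpy())
        pvals.append(het.p_value)
        rows.append({
            "Gene": g,
            "Mutated%_Pan": round(float(mut_pan[g]), 3),
            "Amplified%_Pan": round(float(amp_pan[g]), 3),
            "Entropy": round(normalized_entropy(vec), 3),
            "Tau": round(tau_index(vec), 3),
            "Class": cls,
            "Top_Cancer": top,
            "Second_Cancer": second,
            "Top_vs_Second_Diff(%)": round(diff, 3),
            "Chi2_p": het.p_value,
        })
    out = pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS[:-1])
    out["BH-FDR_q"] = bh_fdr(pvals) if rows else []
    out = out.reindex(columns=LANDSCAPE_COLUMNS)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "landscape.tsv", sep="\t", index=False)
        meta = {
            "mode": "union",
            "cutoffs": vars(cutoffs),
            "bh_family_size": len(rows),
            "n_per_cohort": {str(k): int(v) for k, v in n.items()},
        }
        (outdir / "landscape_meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    return out
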