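"""Expression-module activity and genotype association testing.

Gene-wise z-scores are taken across the pooled cohort (mean 0, sample SD 1
per gene); module activity is the arithmetic mean of member-gene z-scores
per sample.  Activity is then contrasted between genotype groups (e.g. PTEN
loss vs wild type, PIK3CA mutation vs wild type, RICTOR amplification vs
diploid) with a Mann-Whitney U test plus Cliff's delta, and with an OLS
model carrying cancer type as a categorical covariate and HC1 robust
standard errors.  BH-FDR is applied over the emitted table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import CohortAlterationTable, carrier_mask
from .stats import bh_fdr, cliffs_delta, linear_model_robust, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeContrast",
    "read_gmt",
    "pooled_zscores",
    "module_activity",
    "define_genotype_groups",
    "association_tests",
]


@dataclass
class GenotypeContrast:
    """A binary genotype split on one gene.

    ``event`` is one of ``loss`` (mutation or deletion), ``mutation``
    (mutation flag only) or ``amplification`` (GISTIC +1/+2, compared
    against diploid: deleted samples are excluded from the comparator).
    """

    name: str
    gene: str
    event: str


DEFAULT_CONTRASTS = [
    GenotypeContrast("PTEN_loss", "PTEN", "loss"),
    GenotypeContrast("PIK3CA_mut", "PIK3CA", "mutation"),
    GenotypeContrast("RICTOR_amp", "RICTOR", "amplification"),
]


def read_gmt(path: Path | str) -> dict[str, list[str]]:
    """Parse a GMT module file (name, description, members...)."""
    modules: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        modules[parts[0]] = parts[2:]
    return modules


def pooled_zscores(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across the pooled cohort (ddof=1).

    Zero-variance genes cannot be standardized and are dropped with a
    warning.
    """
    if expression.shape[1] < 2:
        raise ValueError("z-scoring needs at least two samples")
    mu = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s): "
            f"{list(expression.index[constant])[:5]}")
        expression = expression.loc[~constant]
        mu, sd = mu[~constant], sd[~constant]
    return expression.sub(mu, axis=0).div(sd, axis=0)


def module_activity(z: pd.DataFrame, members: Sequence[str],
                    module_name: str = "") -> pd.Series:
    """Arithmetic mean of member-gene z-scores, per sample."""
    present = [g for g in members if g in z.index]
    if not present:
        raise ValueError(f"no member of module {module_name!r} present in the z matrix")
    missing = set(members) - set(present)
    if missing:
        logger.info("module %s: %d member(s) absent from expression: %s",
                    module_name, len(missing), sorted(missing))
    return z.loc[present].mean(axis=0)


def define_genotype_groups(
    alterations: CohortAlterationTable, contrast: GenotypeContrast,
) -> pd.Series:
    """Binary labels (1 carrier / 0 comparator / NaN excluded) per sample.

    Amplification contrasts compare against diploid: samples with a
    deletion call on the contrast gene belong to neither group.
    """
    if contrast.gene not in alterations.genes:
        raise ValueError(f"contrast gene {contrast.gene!r} absent from alteration data")
    carriers = carrier_mask(alterations, contrast.gene, contrast.event)
    labels = carriers.astype(float)
    if contrast.event == "amplification":
        deleted = alterations.cna[contrast.gene] < 0
        labels[deleted & ~carriers] = np.nan
    return labels


ACTIVITY_COLUMNS = [
    "Contrast", "Module", "Method", "p", "q (BH-FDR)", "Cliff's δ",
    "Median Diff (1–0)", "N0", "N1", "Median0", "Median1", "IQR0", "IQR1",
    "Model Δ", "Model CI lo", "Model CI hi", "Model p",
]


def association_tests(
    z: pd.DataFrame,
    alterations: CohortAlterationTable,
    modules: dict[str, Sequence[str]],
    contrasts: Optional[Sequence[GenotypeContrast]] = None,
    outdir: Optional[Path | str] = None,
) -> pd.DataFrame:
    """Per contrast x module association table plus the delta-score matrix.

    Each row carries the Mann-Whitney p, Cliff's delta, group medians/IQRs
    and median difference (group1 - group0), and the covariate-adjusted
    model coefficient with its Wald CI.  q-values are BH over the whole
    emitted table; the family size is recorded in the metadata JSON.
    """
    contrasts = list(contrasts) if contrasts is not None else DEFAULT_CONTRASTS
    shared = z.columns.intersection(alterations.samples)
    n_dropped = len(alterations.samples) - len(shared)
    if n_dropped:
        logger.info("dropping %d sample(s) without expression", n_dropped)
    cohort = alterations.cohort_of.reindex(shared)

    scores = {
        name: module_activity(z[shared], members, name)
        for name, members in modules.items()
    }
    rows = []
    for contrast in contrasts:
        labels = define_genotype_groups(alterations, contrast).reindex(shared)
        for mod_name, score in scores.items():
            mask = labels.notna()
            y = score[mask]
            lab = labels[mask]
            g0, g1 = y[lab == 0], y[lab == 1]
            if g0.empty or g1.empty:
                logger.warning("contrast %s has an empty group; skipped", contrast.name)
                continue
            mw = mann_whitney(g0, g1)
            row = {
                "Contrast": contrast.name,
                "Module": mod_name,
                "Method": "Mann–Whitney (Cliff's δ)",
                "p": mw.p_value,
                "Cliff's δ": cliffs_delta(g0, g1),
                "Median Diff (1–0)": float(g1.median() - g0.median()),
                "N0": int(g0.size),
                "N1": int(g1.size),
                "Median0": float(g0.median()),
                "Median1": float(g1.median()),
                "IQR0": float(g0.quantile(0.75) - g0.quantile(0.25)),
                "IQR1": float(g1.quantile(0.75) - g1.quantile(0.25)),
            }
            try:
                design = pd.DataFrame({
                    "genotype": lab.to_numpy(),
                    "cohort": cohort[mask].to_numpy(),
                })
                coefs = linear_model_robust(y.to_numpy(), design)
                row["Model Δ"] = float(coefs.loc["genotype", "estimate"])
                row["Model CI lo"] = float(coefs.loc["genotype", "ci_lo"])
                row["Model CI hi"] = float(coefs.loc["genotype", "ci_hi"])
                row["Model p"] = float(coefs.loc["genotype", "p"])
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("model for %s/%s not estimable: %s",
                               contrast.name, mod_name, exc)
                row.update({"Model Δ": np.nan, "Model CI lo": np.nan,
                            "Model CI hi": np.nan, "Model p": np.nan})
            rows.append(row)

    out = pd.DataFrame(rows)
    if not out.empty:
        out["q (BH-FDR)"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q (BH-FDR)"] = []
    out = out.reindex(columns=ACTIVITY_COLUMNS)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "activity.tsv", sep="\t", index=False)
        delta = out.pivot_table(index="Module", columns="Contrast",
                                values="Model Δ", dropna=False)
        delta.to_csv(outdir / "delta_matrix.tsv", sep="\t")
        meta = {"bh_family_size": int(len(out)),
                "n_samples_scored": int(len(shared)),
                "n_samples_dropped_no_expression": int(n_dropped)}
        (outdir / "activity_meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    return out
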