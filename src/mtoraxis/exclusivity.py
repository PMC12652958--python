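"""Mutual exclusivity and co-occurrence of pathway alterations.

Samples are binarized per gene under a role-aware rule — altered =
mutation OR amplification for oncogenes, mutation OR deletion for tumor
suppressors, mutation OR any non-zero copy-number call for unspecified
genes — then every unordered gene pair is tested for independence on its
2x2 table, choosing Fisher's exact test when any expected count is below 5
and the Yates-corrected chi-square otherwise.  Odds ratios use the
Haldane-Anscombe +0.5 correction when a cell is zero (estimate only, never
the exact p).  BH-FDR runs over all emitted pairs; negative log2 odds
ratios indicate mutual exclusivity, positive co-occurrence.  The signed
log2OR matrix is clipped to +/-1.6 for display and ordered by hierarchical
clustering of the signed association profiles.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import CohortAlterationTable, default_role
from .stats import bh_fdr, select_2x2_test

logger = logging.getLogger(__name__)

__all__ = [
    "binarize_alterations",
    "pairwise_association",
    "association_matrix",
    "plot_heatmap",
    "write_exclusivity_outputs",
]

LOG2OR_CLIP = 1.6
Q_DESATURATE = 0.10


def binarize_alterations(
    alterations: CohortAlterationTable,
    roles: Optional[dict[str, str]] = None,
    encoding: str = "role",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Samples x genes boolean matrix under the role-aware encoding.

    ``encoding='mutation'`` or ``'scna'`` restrict to one event class (the
    sensitivity reruns); the default combines mutation with the
    role-appropriate copy-number event.  Returns the matrix and a per-gene
    provenance map recording which rule produced each column.
    """
    mut, cna = alterations.mutations, alterations.cna
    out = pd.DataFrame(False, index=mut.index, columns=mut.columns)
    provenance: dict[str, str] = {}
    for g in mut.columns:
        role = (roles or {}).get(g, default_role(g))
        if encoding == "mutation":
            out[g] = mut[g]
            provenance[g] = "mutation_only"
            continue
        if role == "oncogene":
            cn_event = cna[g] > 0
            provenance[g] = "mutation|amplification"
        elif role == "tumor_suppressor":
            cn_event = cna[g] < 0
            provenance[g] = "mutation|deletion"
        else:
            cn_event = cna[g] != 0
            provenance[g] = "mutation|any_cna (role unspecified)"
            logger.info("gene %s has no annotated role; using any non-zero CNA", g)
        if encoding == "scna":
            out[g] = cn_event
            provenance[g] = provenance[g].split("|")[1].split(" ")[0] + "_only"
        elif encoding == "role":
            out[g] = mut[g] | cn_event
        else:
            raise ValueError("encoding must be 'role', 'mutation' or 'scna'")
    return out, provenance


PAIR_COLUMNS = [
    "geneA", "geneB", "n11", "n10", "n01", "n00", "odds_ratio",
    "log2_odds_ratio", "log2_odds_ratio_display", "direction", "test",
    "statistic", "p", "q", "n_evaluable", "haldane_corrected", "evaluable",
]


def pairwise_association(
    binary: pd.DataFrame,
    genes: Optional[Sequence[str]] = None,
    clip: float = LOG2OR_CLIP,
) -> pd.DataFrame:
    """All-pairs 2x2 association tests with BH-FDR over the emitted table."""
    genes = list(genes) if genes is not None else list(binary.columns)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    rows = []
    for i, a in enumerate(genes):
        xa = binary[a].to_numpy()
        for b in genes[i + 1:]:
            xb = binary[b].to_numpy()
            n11 = int(np.sum(xa & xb))
            n10 = int(np.sum(xa & ~xb))
            n01 = int(np.sum(~xa & xb))
            n00 = int(np.sum(~xa & ~xb))
            res = select_2x2_test([[n11, n10], [n01, n00]])
            or_ = res.effect
            l2 = math.log2(or_) if or_ is not None and or_ > 0 else np.nan
            rows.append({
                "geneA": a, "geneB": b,
                "n11": n11, "n10": n10, "n01": n01, "n00": n00,
                "odds_ratio": or_ if or_ is not None else np.nan,
                "log2_odds_ratio": l2,
                "log2_odds_ratio_display": float(np.clip(l2, -clip, clip))
                if not np.isnan(l2) else np.nan,
                "direction": ("co-occurrence" if l2 > 0
                              else "mutual_exclusivity" if l2 < 0
                              else "independent") if not np.isnan(l2) else "non-evaluable",
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p_value,
                "n_evaluable": res.n_evaluable,
                "haldane_corrected": res.haldane_corrected,
                "evaluable": res.evaluable,
            })
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.reindex(columns=PAIR_COLUMNS)


def association_matrix(
    records: pd.DataFrame, clip: float = LOG2OR_CLIP, q_cut: float = Q_DESATURATE,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Symmetric signed log2OR matrix, significance mask, and clustering order.

    Display values are clipped to +/-clip; the diagonal and non-evaluable
    pairs stay NaN.  The mask marks cells with q >= q_cut (rendered
    desaturated).  Row/column order comes from average-linkage hierarchical
    clustering on Euclidean distances between signed association profiles
    (NaNs treated as 0 for the distance computation only).
    """
    genes = sorted(set(records["geneA"]) | set(records["geneB"]))
    mat = pd.DataFrame(np.nan, index=genes, columns=genes)
    mask = pd.DataFrame(False, index=genes, columns=genes)
    for row in records.itertuples(index=False):
        if not row.evaluable or np.isnan(row.log2_odds_ratio):
            continue
        v = float(np.clip(row.log2_odds_ratio, -clip, clip))
        mat.loc[row.geneA, row.geneB] = v
        mat.loc[row.geneB, row.geneA] = v
        insig = row.q >= q_cut
        mask.loc[row.geneA, row.geneB] = insig
        mask.loc[row.geneB, row.geneA] = insig

    if len(genes) > 2:
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import pdist
        profiles = mat.fillna(0.0).to_numpy()
        order = leaves_list(average(pdist(profiles, metric="euclidean")))
        genes_ordered = [genes[i] for i in order]
    else:
        genes_ordered = genes
    mat = mat.loc[genes_ordered, genes_ordered]
    mask = mask.loc[genes_ordered, genes_ordered]
    return mat, mask, genes_ordered


def plot_heatmap(
    mat: pd.DataFrame, mask: pd.DataFrame, path: Path | str,
    clip: float = LOG2OR_CLIP,
) -> None:
    """Diverging heatmap of the clipped log2OR matrix; insignificant cells faded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.5 * len(mat) + 2, 0.5 * len(mat) + 2))
    data = mat.to_numpy(dtype=float)
    im = ax.imshow(data, cmap="RdBu_r", vmin=-clip, vmax=clip)
    faded = np.where(mask.to_numpy() & ~np.isnan(data), 0.55, 0.0)
    ax.imshow(np.ones_like(data), cmap="Greys", vmin=0, vmax=1,
              alpha=faded)  # desaturate q >= 0.10 cells
    ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat)), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log2 odds ratio (clipped)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_exclusivity_outputs(
    records: pd.DataFrame, outdir: Path | str, heatmap: bool = True,
) -> None:
    """Write pairs.tsv, log2or_matrix.tsv, clustering_order.txt (+ heatmap)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    mat, mask, order = association_matrix(records)
    mat.to_csv(outdir / "log2or_matrix.tsv", sep="\t")
    (outdir / "clustering_order.txt").write_text("\n".join(order) + "\n")
    if heatmap:
        plot_heatmap(mat, mask, outdir / "log2or_heatmap.png")
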