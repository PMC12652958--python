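"""Confidence-filtered interaction graph and random-walk-with-restart scoring.

Edges from a STRING-style table are filtered at a combined-score cutoff
(default 0.7, with 0.4 as the sensitivity setting), optionally after
down-weighting the text-mining channel and recombining the remaining
channel scores as 1 - prod(1 - s_c).  The walk operator is either the
symmetric degree normalization D^{-1/2} A D^{-1/2} (default; weighted
degrees) or the row-stochastic D^{-1} A, which makes the iteration exactly
personalized PageRank.  Scores are iterated to stationarity with restart
probability alpha (default 0.75), L1-renormalized every step, and can be
verified against the direct linear solve.

Downstream, scores feed degree-matched permutation nulls and the
"non-mutated nomination" filter: candidates above a pan-cancer alteration
prevalence cutoff (default 3%, counting non-synonymous mutation or
amplification) or carrying flagged hotspot variants are excluded from the
filtered ranking.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "load_interaction_graph",
    "filter_graph",
    "build_kernel",
    "propagate",
    "propagate_solve",
    "degree_matched_null",
    "filter_nonmutated",
]

STRING_CHANNELS = ["textmining", "experimental", "database", "coexpression"]


@dataclass
class PropagationConfig:
    """Walk and filtering parameters; defaults are the primary setting."""

    alpha: float = 0.75                 # restart probability
    kernel: str = "symmetric"           # or "stochastic"
    tolerance: float = 1e-10
    max_iterations: int = 1000
    combined_min: float = 0.7           # sensitivity setting: 0.4
    textmining_weight: float = 1.0      # 1 = keep channel as published
    seeds: list[str] = field(default_factory=list)
    neighborhood_hops: Optional[int] = None

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.kernel not in ("symmetric", "stochastic"):
            raise ValueError("kernel must be 'symmetric' or 'stochastic'")
        if not (0 <= self.textmining_weight <= 1):
            raise ValueError("textmining_weight must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Graph loading / filtering
# ---------------------------------------------------------------------------

def load_interaction_graph(path: Path | str, config: PropagationConfig) -> nx.Graph:
    """Read a STRING-style edge table and apply confidence filtering.

    Scores on the 0-1000 integer scale are auto-detected and rescaled to
    [0, 1].  Duplicate A-B / B-A rows collapse keeping the maximum score;
    self-loops are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(df.columns):
        raise ValueError(
            "unknown network schema; expected columns protein1, protein2, "
            f"combined_score (+ optional channels {STRING_CHANNELS}); got {list(df.columns)}")
    channels = [c for c in STRING_CHANNELS if c in df.columns]
    score_cols = channels + ["combined_score"]
    if df[score_cols].to_numpy().max() > 1.0:  # 0-1000 integer scale
        df[score_cols] = df[score_cols] / 1000.0

    g = nx.Graph()
    for row in df.itertuples(index=False):
        u, v = row.protein1, row.protein2
        if u == v:
            continue
        attrs = {c: float(getattr(row, c)) for c in score_cols}
        if g.has_edge(u, v):  # keep the higher-confidence duplicate
            if attrs["combined_score"] <= g[u][v]["combined_score"]:
                continue
        g.add_edge(u, v, **attrs)
    return filter_graph(g, config)


def filter_graph(g: nx.Graph, config: PropagationConfig) -> nx.Graph:
    """Apply text-mining down-weighting and the combined-score cutoff."""
    config.validate()
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        d = dict(d)
        if config.textmining_weight < 1.0 and "textmining" in d:
            d["textmining"] = d["textmining"] * config.textmining_weight
            chans = [d[c] for c in STRING_CHANNELS if c in d]
            d["combined_score"] = 1.0 - float(np.prod([1.0 - s for s in chans]))
        if d["combined_score"] >= config.combined_min:
            out.add_edge(u, v, **d)
    out.remove_nodes_from(list(nx.isolates(out)))
    if out.number_of_edges() == 0:
        raise ValueError("no edges survive the combined-score cutoff")
    if config.neighborhood_hops is not None:
        seeds = [s for s in config.seeds if s in out]
        keep = set(seeds)
        frontier = set(seeds)
        for _ in range(config.neighborhood_hops):
            frontier = {nb for u in frontier for nb in out.neighbors(u)} - keep
            keep |= frontier
        out = out.subgraph(keep).copy()
    return out


# ---------------------------------------------------------------------------
# Kernels and propagation
# ---------------------------------------------------------------------------

def build_kernel(
    g: nx.Graph, kernel: str = "symmetric",
) -> tuple[np.ndarray, list[str]]:
    """Degree-normalized walk operator and its node order.

    symmetric: D^{-1/2} A D^{-1/2}; stochastic: D^{-1} A with columns of the
    returned matrix acting on score vectors (K[i, j] = transition j -> i).
    Degrees are weighted by combined score.  Zero-degree nodes are dropped
    with a warning.
    """
    nodes = [n for n in g.nodes if g.degree(n, weight="combined_score") > 0]
    if len(nodes) < g.number_of_nodes():
        warnings.warn(f"dropping {g.number_of_nodes() - len(nodes)} zero-degree node(s)")
    A = nx.to_numpy_array(g, nodelist=nodes, weight="combined_score")
    deg = A.sum(axis=1)
    if kernel == "symmetric":
        d_inv_sqrt = 1.0 / np.sqrt(deg)
        K = (A * d_inv_sqrt).T * d_inv_sqrt  # D^-1/2 A D^-1/2 (symmetric)
    elif kernel == "stochastic":
        K = (A / deg[:, None]).T  # column j sums to 1: mass leaving node j
    else:
        raise ValueError("kernel must be 'symmetric' or 'stochastic'")
    return K, nodes


def _seed_vector(nodes: Sequence[str], seeds: Sequence[str]) -> np.ndarray:
    present = [s for s in seeds if s in set(nodes)]
    missing = set(seeds) - set(present)
    if missing:
        logger.warning("seed(s) absent from graph, mass reallocated: %s", sorted(missing))
    if not present:
        raise ValueError("no seed node present in the graph")
    s = np.zeros(len(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    for name in present:
        s[idx[name]] = 1.0 / len(present)
    return s


def propagate(
    g: nx.Graph, config: PropagationConfig,
) -> tuple[pd.Series, dict]:
    """Random walk with restart to stationarity.

    Iterates p <- (1 - alpha) K p + alpha s from p = s with per-step L1
    renormalization (the symmetric kernel is not mass-preserving), stopping
    when the L1 change drops below the tolerance.  Returns non-negative
    scores summing to 1 plus iteration diagnostics.
    """
    config.validate()
    K, nodes = build_kernel(g, config.kernel)
    s = _seed_vector(nodes, config.seeds)
    # Iterate the raw affine map (a contraction: the normalized kernel's
    # spectral radius is <= 1 and alpha > 0) and report the L1-normalized
    # vector; the raw fixed point is exactly alpha (I - (1-alpha) K)^-1 s.
    x = s.copy()
    p = x / x.sum()
    for it in range(1, config.max_iterations + 1):
        x = (1.0 - config.alpha) * (K @ x) + config.alpha * s
        nxt = x / x.sum()
        delta = float(np.abs(nxt - p).sum())
        p = nxt
        if delta < config.tolerance:
            break
    else:
        raise RuntimeError(
            f"propagation did not converge in {config.max_iterations} "
            f"iterations (residual {delta:.3e})")
    diagnostics = {"iterations": it, "residual": delta, "alpha": config.alpha,
                   "kernel": config.kernel, "n_nodes": len(nodes),
                   "combined_min": config.combined_min}
    return pd.Series(p, index=nodes).sort_values(ascending=False), diagnostics


def propagate_solve(g: nx.Graph, config: PropagationConfig) -> pd.Series:
    """Closed-form stationary scores: p = alpha (I - (1-alpha) K)^{-1} s.

    Renormalized to sum 1; the iterative solver must agree with this on any
    graph small enough to invert.
    """
    K, nodes = build_kernel(g, config.kernel)
    s = _seed_vector(nodes, config.seeds)
    p = config.alpha * np.linalg.solve(
        np.eye(len(nodes)) - (1.0 - config.alpha) * K, s)
    p = np.maximum(p, 0.0)
    return pd.Series(p / p.sum(), index=nodes).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Degree-matched nulls
# ---------------------------------------------------------------------------

def degree_matched_null(
    g: nx.Graph,
    config: PropagationConfig,
    n_perm: int = 200,
    n_bins: int = 10,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Empirical per-node enrichment p-values from degree-matched seed swaps.

    Each permutation replaces every seed with a uniform draw from the
    seed's degree-quantile bin (bins widened when they hold fewer than two
    candidates).  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    observed, _ = propagate(g, config)
    rng = np.random.default_rng(rng_seed)
    nodes = list(observed.index)
    deg = np.array([g.degree(n, weight="combined_score") for n in nodes])
    edges = np.quantile(deg, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(edges, deg, side="right") - 1, 0, n_bins - 1)
    bins: dict[int, list[str]] = {}
    for n, b in zip(nodes, bin_of):
        bins.setdefault(int(b), []).append(n)
    node_bin = dict(zip(nodes, (int(b) for b in bin_of)))

    def candidates(seed: str) -> list[str]:
        b = node_bin[seed]
        pool = list(bins.get(b, []))
        width = 1
        while len(pool) < 2 and width <= n_bins:
            warnings.warn(f"degree bin for seed {seed} too small; widening")
            pool = [n for n in nodes if abs(node_bin[n] - b) <= width]
            width += 1
        return pool

    seeds_in = [s for s in config.seeds if s in set(nodes)]
    exceed = np.zeros(len(nodes))
    from dataclasses import replace
    for _ in range(n_perm):
        null_seeds = [str(rng.choice(candidates(s))) for s in seeds_in]
        null_scores, _ = propagate(g, replace(config, seeds=null_seeds))
        exceed += (null_scores.reindex(observed.index).to_numpy()
                   >= observed.to_numpy() - 1e-15)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame({"score": observed, "empirical_p": p,
                         "degree": deg}, index=observed.index)


# ---------------------------------------------------------------------------
# Non-mutated nomination filter
# ---------------------------------------------------------------------------

NOMINATION_COLUMNS = [
    "filtered_rank", "gene", "page_rank_score", "pan_cancer_alteration_pct",
    "degree", "source_support_count", "seed", "hotspot_excluded",
]


def filter_nonmutated(
    scores: pd.Series,
    alteration_pct: pd.Series,
    graph: nx.Graph,
    seeds: Sequence[str] = (),
    hotspot_genes: Sequence[str] = (),
    cutoff_pct: float = 3.0,
    source_support: Optional[pd.Series] = None,
    outdir: Optional[Path | str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank candidates by propagation score and drop frequently altered genes.

    ``alteration_pct`` is the pooled pan-cancer percentage of samples with a
    non-synonymous mutation or amplification.  Genes above ``cutoff_pct``,
    seed genes, and hotspot-flagged genes leave the filtered list (hotspot
    rows are reported in a side table).  Score ties break toward lower
    degree, then the lexicographically smaller symbol.  Returns
    (filtered nominations, full unfiltered ranking).
    """
    hotspots = set(hotspot_genes)
    seeds = set(seeds)
    rows = []
    n_missing = 0
    for gene, score in scores.items():
        pct = alteration_pct.get(gene, np.nan)
        if pd.isna(pct):
            n_missing += 1
        rows.append({
            "gene": gene,
            "page_rank_score": float(score),
            "pan_cancer_alteration_pct": float(pct) if pd.notna(pct) else np.nan,
            "degree": int(graph.degree(gene)),
            "source_support_count": (
                int(source_support[gene]) if source_support is not None
                and gene in source_support.index else 0),
            "seed": gene in seeds,
            "hotspot_excluded": gene in hotspots,
        })
    if n_missing:
        logger.warning(
            "%d gene(s) lack alteration data; retained with missing pct", n_missing)
    full = pd.DataFrame(rows).sort_values(
        by=["page_rank_score", "degree", "gene"],
        ascending=[False, True, True], kind="mergesort",
    ).reset_index(drop=True)
    full.insert(0, "rank", np.arange(1, len(full) + 1))

    keep = (
        ~full["seed"]
        & ~full["hotspot_excluded"]
        & (full["pan_cancer_alteration_pct"].isna()
           | (full["pan_cancer_alteration_pct"] <= cutoff_pct))
    )
    filtered = full.loc[keep].drop(columns="rank").reset_index(drop=True)
    filtered.insert(0, "filtered_rank", np.arange(1, len(filtered) + 1))
    filtered = filtered.reindex(columns=NOMINATION_COLUMNS)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        full.to_csv(outdir / "propagation_full.tsv", sep="\t", index=False)
        filtered.to_csv(outdir / "nominations.tsv", sep="\t", index=False)
        full.loc[full["hotspot_excluded"]].to_csv(
            outdir / "hotspot_excluded.tsv", sep="\t", index=False)
    return filtered, full
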