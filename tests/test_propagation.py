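"""Graph filtering, kernels, RWR oracle equivalence, nulls, nomination filter."""

from dataclasses import replace

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mtoraxis import (
    PropagationConfig,
    build_kernel,
    degree_matched_null,
    filter_nonmutated,
    load_interaction_graph,
    propagate,
    propagate_solve,
)
from mtoraxis.propagation import filter_graph
from mtoraxis.simulate import SEED_GENES


def path3(w=1.0):
    g = nx.Graph()
    g.add_edge("a", "b", combined_score=w)
    g.add_edge("b", "c", combined_score=w)
    return g


# ---------------------------------------------------------------------------
# Loading / filtering
# ---------------------------------------------------------------------------

def test_strict_threshold_removes_edge(tmp_path):
    df = pd.DataFrame({
        "protein1": ["a", "b"], "protein2": ["b", "c"],
        "textmining": [0, 0], "experimental": [690, 710],
        "database": [0, 0], "coexpression": [0, 0],
        "combined_score": [690, 710],
    })
    path = tmp_path / "net.tsv"
    df.to_csv(path, sep="\t", index=False)
    g = load_interaction_graph(path, PropagationConfig(combined_min=0.7))
    assert not g.has_edge("a", "b") and g.has_edge("b", "c")


def test_textmining_downweight_zero_prunes_tm_only_edge(tmp_path):
    df = pd.DataFrame({
        "protein1": ["a", "a"], "protein2": ["b", "c"],
        "textmining": [0.95, 0.0], "experimental": [0.0, 0.95],
        "database": [0.0, 0.0], "coexpression": [0.0, 0.0],
        "combined_score": [0.95, 0.95],
    })
    path = tmp_path / "net.tsv"
    df.to_csv(path, sep="\t", index=False)
    cfg = PropagationConfig(combined_min=0.7, textmining_weight=0.0)
    g = load_interaction_graph(path, cfg)
    assert not g.has_edge("a", "b") and g.has_edge("a", "c")


def test_duplicate_edges_collapse_keeping_max(tmp_path):
    df = pd.DataFrame({
        "protein1": ["a", "b"], "protein2": ["b", "a"],
        "combined_score": [750, 900],
    })
    path = tmp_path / "net.tsv"
    df.to_csv(path, sep="\t", index=False)
    g = load_interaction_graph(path, PropagationConfig())
    assert g["a"]["b"]["combined_score"] == pytest.approx(0.9)


def test_unknown_schema_rejected(tmp_path):
    path = tmp_path / "net.tsv"
    pd.DataFrame({"x": [1]}).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="schema"):
        load_interaction_graph(path, PropagationConfig())


def test_filtered_counts_match_generator_truth(study):
    g = study["graph"]
    cfg = PropagationConfig(combined_min=0.7)
    gf = filter_graph(g, cfg)
    expected = sum(1 for _, _, d in g.edges(data=True)
                   if d["combined_score"] >= 0.7)
    assert gf.number_of_edges() == expected


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def test_two_node_symmetric_kernel():
    g = nx.Graph()
    g.add_edge("a", "b", combined_score=1.0)
    K, nodes = build_kernel(g, "symmetric")
    np.testing.assert_allclose(K, [[0, 1], [1, 0]])


def test_stochastic_columns_sum_to_one():
    K, _ = build_kernel(path3(0.7), "stochastic")
    np.testing.assert_allclose(K.sum(axis=0), 1.0)


def test_regular_graph_kernels_proportional():
    g = nx.cycle_graph(6)
    for u, v in g.edges:
        g[u][v]["combined_score"] = 1.0
    Ks, _ = build_kernel(g, "symmetric")
    Kt, _ = build_kernel(g, "stochastic")
    np.testing.assert_allclose(Ks, Kt, atol=1e-12)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def test_single_node_seed_scores_one():
    g = nx.Graph()
    g.add_edge("s", "t", combined_score=1.0)
    scores, _ = propagate(g, PropagationConfig(seeds=["s", "t"]))
    assert scores.sum() == pytest.approx(1.0)


def test_alpha_one_returns_seed_vector():
    scores, _ = propagate(path3(), PropagationConfig(alpha=1.0, seeds=["a"]))
    assert scores["a"] == pytest.approx(1.0)
    assert scores[["b", "c"]].sum() == pytest.approx(0.0, abs=1e-12)


def test_path_graph_matches_linear_solve():
    cfg = PropagationConfig(alpha=0.75, kernel="stochastic", seeds=["a"])
    it, _ = propagate(path3(), cfg)
    solved = propagate_solve(path3(), cfg)
    assert np.abs(it.sort_index() - solved.sort_index()).max() < 1e-10


@pytest.mark.parametrize("kernel", ["symmetric", "stochastic"])
@pytest.mark.parametrize("alpha", [0.5, 0.75, 0.9])
def test_oracle_equivalence_random_graphs(kernel, alpha, rng):
    for _ in range(10):
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        for u, v in g.edges:
            g[u][v]["combined_score"] = float(rng.uniform(0.1, 1.0))
        seeds = list(g.nodes)[:2]
        cfg = PropagationConfig(alpha=alpha, kernel=kernel, seeds=seeds,
                                combined_min=0.0)
        it, _ = propagate(g, cfg)
        solved = propagate_solve(g, cfg)
        assert np.abs(it.sort_index() - solved.sort_index()).max() < 1e-8


def test_stochastic_kernel_equals_networkx_pagerank(study):
    g = filter_graph(study["graph"], PropagationConfig())
    cfg = PropagationConfig(kernel="stochastic", seeds=SEED_GENES)
    scores, _ = propagate(g, cfg)
    pers = {n: (1 / len(SEED_GENES) if n in SEED_GENES else 0) for n in g}
    pr = nx.pagerank(g, alpha=1 - cfg.alpha, personalization=pers,
                     weight="combined_score", tol=1e-12, max_iter=1000)
    diff = max(abs(scores[n] - pr[n]) for n in scores.index)
    assert diff < 1e-8


def test_scores_nonnegative_sum_one(study):
    g = filter_graph(study["graph"], PropagationConfig())
    scores, diag = propagate(g, PropagationConfig(seeds=SEED_GENES))
    assert scores.min() >= 0
    assert scores.sum() == pytest.approx(1.0)
    assert diag["iterations"] >= 1


def test_missing_seeds_reallocate_and_all_missing_raises(study):
    g = filter_graph(study["graph"], PropagationConfig())
    scores, _ = propagate(g, PropagationConfig(seeds=SEED_GENES + ["NOPE"]))
    assert scores.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="seed"):
        propagate(g, PropagationConfig(seeds=["NOPE"]))


def test_rank_stability_across_alpha(study):
    from scipy.stats import spearmanr
    g = filter_graph(study["graph"], PropagationConfig())
    cfg = PropagationConfig(seeds=SEED_GENES)
    s05, _ = propagate(g, replace(cfg, alpha=0.5))
    s09, _ = propagate(g, replace(cfg, alpha=0.9))
    rho = spearmanr(s05, s09.reindex(s05.index)).statistic
    assert rho > 0.8


# ---------------------------------------------------------------------------
# Degree-matched nulls
# ---------------------------------------------------------------------------

def test_null_p_bounds_and_planted_enrichment(study):
    g = filter_graph(study["graph"], PropagationConfig())
    cfg = PropagationConfig(seeds=SEED_GENES)
    nulls = degree_matched_null(g, cfg, n_perm=49, rng_seed=1)
    assert nulls["empirical_p"].between(1 / 50, 1.0).all()
    planted = [n for n in study["truth"].planted_community if n in nulls.index]
    background = nulls.index.difference(planted)
    assert (nulls.loc[planted, "empirical_p"].median()
            < nulls.loc[background, "empirical_p"].median())


# ---------------------------------------------------------------------------
# Non-mutated nomination filter
# ---------------------------------------------------------------------------

def test_filter_cutoff_and_tie_break():
    g = nx.Graph()
    for a, b in [("x", "y"), ("y", "z"), ("x", "z"), ("w", "x")]:
        g.add_edge(a, b, combined_score=1.0)
    scores = pd.Series({"x": 0.4, "y": 0.3, "z": 0.3, "w": 0.0})
    pct = pd.Series({"x": 3.5, "y": 0.5, "z": 0.5, "w": 2.0})
    filtered, full = filter_nonmutated(scores, pct, g)
    assert "x" not in set(filtered["gene"])          # 3.5% > 3% cutoff
    # score tie y/z: lower degree first (both degree 2) then lexicographic
    assert list(filtered["gene"]) == ["y", "z", "w"]
    assert list(filtered["filtered_rank"]) == [1, 2, 3]
    assert len(full) == 4


def test_hotspot_flag_excludes_but_reports(tmp_path):
    g = nx.Graph()
    g.add_edge("a", "b", combined_score=1.0)
    scores = pd.Series({"a": 0.6, "b": 0.4})
    pct = pd.Series({"a": 1.0, "b": 1.0})
    filtered, full = filter_nonmutated(
        scores, pct, g, hotspot_genes=["a"], outdir=tmp_path)
    assert list(filtered["gene"]) == ["b"]
    side = pd.read_csv(tmp_path / "hotspot_excluded.tsv", sep="\t")
    assert list(side["gene"]) == ["a"]


def test_missing_alteration_pct_retained_flagged():
    g = nx.Graph()
    g.add_edge("a", "b", combined_score=1.0)
    scores = pd.Series({"a": 0.6, "b": 0.4})
    pct = pd.Series({"a": 1.0})
    filtered, _ = filter_nonmutated(scores, pct, g)
    assert "b" in set(filtered["gene"])
    assert filtered.set_index("gene").loc["b", "pan_cancer_alteration_pct"] != \
        filtered.set_index("gene").loc["b", "pan_cancer_alteration_pct"]  # NaN
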