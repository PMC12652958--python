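import numpy as np
import pytest

from mtoraxis import (
    default_config,
    simulate_alteration_cohorts,
    simulate_expression,
    simulate_interaction_network,
    write_fixture_set,
)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across tests (seed 7)."""
    cfg = default_config(rng_seed=7)
    alt, truth = simulate_alteration_cohorts(cfg)
    expr, labels = simulate_expression(alt, cfg)
    graph, net_truth = simulate_interaction_network(cfg)
    truth.planted_community = net_truth.planted_community
    truth.high_alteration_genes = net_truth.high_alteration_genes
    return {"config": cfg, "alterations": alt, "truth": truth,
            "expression": expr, "labels": labels, "graph": graph}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Full on-disk fixture set written by the generator (seed 7)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    paths = write_fixture_set(outdir, default_config(rng_seed=7))
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(0)
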