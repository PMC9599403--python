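"""Shared fixtures: tiny hand-built networks and a synthetic benchmark."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from planknet.netinfer import (
    BipartiteNetwork,
    NetworkConfig,
    permutation_pvalues,
    sparcc_correlations,
)
from planknet.synthdata import (
    GeneratorConfig,
    PlantedEdge,
    SyntheticTruth,
    demo_truth,
    generate_community,
    generate_environment,
    phyto_names,
    write_fixture,
    zoo_names,
)
from planknet.tables_io import combine_tables


def make_net(edges, guilds, taxon_group=None, r=0.5, p=0.01):
    """Build a BipartiteNetwork from explicit edges and guild labels.

    ``edges`` may be (u, v) or (u, v, r) tuples.
    """
    g = nx.Graph()
    for e in edges:
        u, v = e[0], e[1]
        w = e[2] if len(e) > 2 else r
        g.add_edge(u, v, r=w, p=p, weight=abs(w), sign=1 if w >= 0 else -1)
    for n in g.nodes:
        g.nodes[n]["guild"] = guilds[n]
        g.nodes[n]["taxon_group"] = (taxon_group or {}).get(n, "")
    return BipartiteNetwork(g)


def complete_bipartite_net(n_a=4, n_b=4):
    guilds = {}
    edges = []
    a_nodes = [f"p{i}" for i in range(n_a)]
    b_nodes = [f"z{i}" for i in range(n_b)]
    for a in a_nodes:
        guilds[a] = "phytoplankton"
    for b in b_nodes:
        guilds[b] = "zooplankton"
    for a in a_nodes:
        for b in b_nodes:
            edges.append((a, b))
    return make_net(edges, guilds)


def star_net(n_leaves=4):
    guilds = {"hub": "phytoplankton"}
    edges = []
    for i in range(n_leaves):
        leaf = f"z{i}"
        guilds[leaf] = "zooplankton"
        edges.append(("hub", leaf))
    return make_net(edges, guilds)


def random_bipartite_net(rng, n_a=6, n_b=6, p_edge=0.4):
    """A random cross-guild network with at least one edge."""
    while True:
        guilds = {}
        edges = []
        for i in range(n_a):
            guilds[f"p{i}"] = "phytoplankton"
        for j in range(n_b):
            guilds[f"z{j}"] = "zooplankton"
        for i in range(n_a):
            for j in range(n_b):
                if rng.random() < p_edge:
                    edges.append((f"p{i}", f"z{j}", float(rng.uniform(0.3, 1.0))))
        if edges:
            return make_net(edges, guilds)


# ---------------------------------------------------------------------------
# Synthetic benchmark: 30 species, 200 samples, planted cross-guild edges
# ---------------------------------------------------------------------------

BENCHMARK_N_PLANTED = 10


def benchmark_truth(strength=0.9):
    p = phyto_names(15)
    z = zoo_names(15)
    edges = [
        PlantedEdge(p[i], z[i], strength, -1 if i % 5 == 4 else 1, "smaller")
        for i in range(BENCHMARK_N_PLANTED)
    ]
    return SyntheticTruth(
        guild_sizes={"phytoplankton": 15, "zooplankton": 15},
        planted_edges=edges,
        env_coupled_species={},
        density_ratio=2.0,
    )


@pytest.fixture(scope="session")
def benchmark_config():
    return GeneratorConfig(n_samples=200, n_sites=6, seed=42)


@pytest.fixture(scope="session")
def benchmark_tables(benchmark_config):
    return generate_community(benchmark_config, benchmark_truth())


@pytest.fixture(scope="session")
def benchmark_combined(benchmark_tables):
    return combine_tables(benchmark_tables.phyto, benchmark_tables.zoo_smaller)


@pytest.fixture(scope="session")
def benchmark_correlations(benchmark_combined):
    cfg = NetworkConfig(seed=7, n_permutations=100)
    corr = sparcc_correlations(benchmark_combined, cfg)
    return permutation_pvalues(benchmark_combined, corr, cfg)


# ---------------------------------------------------------------------------
# Small on-disk fixture for CLI / pipeline tests
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    directory = tmp_path_factory.mktemp("fixture")
    config = GeneratorConfig(n_samples=80, n_sites=4, seed=11,
                             zero_inflation=0.05)
    truth = demo_truth(n_phyto=12, n_zoo=10, n_edges_smaller=6,
                       n_edges_bigger=2, env_couplings={})
    tables = generate_community(config, truth)
    env = generate_environment(config, truth)
    write_fixture(tables, env, truth, directory)
    return directory
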