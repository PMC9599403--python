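"""Network-level topological indices and per-node connectivity.

Linkage density is the quantitative (Shannon) version computed on |r| edge
weights: for each node the effective number of partners is exp of the Shannon
entropy of its weight distribution, and the linkage density is half the sum,
over both guilds, of effective partner numbers weighted by each node's share
of the total edge weight.  Weighted connectance is linkage density divided by
network size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .netinfer import BipartiteNetwork

__all__ = [
    "TopologyReport", "network_level_metrics", "node_connectivity",
    "weighted_connectance", "bipartite_clustering", "linkage_density",
]


@dataclass
class TopologyReport:
    """Machine twin of a network summary table row."""

    network_size: int = 0
    links: int = 0
    prop_negative: float = 0.0
    links_per_species: float = 0.0
    cluster_coefficient: float = 0.0
    linkage_density: float = 0.0
    weighted_connectance: float = 0.0
    guild_counts: dict = field(default_factory=dict)
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "network_size": self.network_size,
            "links": self.links,
            "prop_negative": self.prop_negative,
            "links_per_species": self.links_per_species,
            "cluster_coefficient": self.cluster_coefficient,
            "linkage_density": self.linkage_density,
            "weighted_connectance": self.weighted_connectance,
            "guild_counts": dict(self.guild_counts),
            "empty": self.empty,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def weighted_connectance(linkage_density: float, network_size: int) -> float:
    """The defining ratio identity: linkage density over network size."""
    return linkage_density / network_size


def node_connectivity(net: BipartiteNetwork) -> dict:
    """Connectivity (= number of links) per node."""
    return dict(net.graph.degree())


def bipartite_clustering(net: BipartiteNetwork) -> float:
    """Mean pairwise bipartite clustering coefficient.

    Uses the neighborhood-overlap (Jaccard) pairwise coefficient
    cc(u, v) = |N(u) & N(v)| / |N(u) | N(v)| between same-guild nodes at
    distance two, averaged per node and then over nodes.
    """
    if net.empty:
        return 0.0
    cc = nx.algorithms.bipartite.clustering(net.graph, mode="dot")
    return float(np.mean(list(cc.values())))


def linkage_density(net: BipartiteNetwork) -> float:
    """Quantitative linkage density on |r| edge weights."""
    if net.empty:
        return 0.0
    g = net.graph
    total_weight = sum(d["weight"] for _, _, d in g.edges(data=True))
    ld = 0.0
    for guild in net.guilds:
        for node in net.nodes_in_guild(guild):
            w = np.array([g.edges[node, nb]["weight"]
                          for nb in g.neighbors(node)], dtype=float)
            strength = w.sum()
            if strength <= 0:
                continue
            p = w / strength
            entropy = -np.sum(p * np.log(p))
            effective_partners = np.exp(entropy)
            ld += (strength / total_weight) * effective_partners
    return 0.5 * ld


def network_level_metrics(net: BipartiteNetwork) -> TopologyReport:
    """Compute the full topology report for one network."""
    if net.empty:
        return TopologyReport(empty=True)
    size = net.n_nodes
    links = net.n_edges
    ld = linkage_density(net)
    return TopologyReport(
        network_size=size,
        links=links,
        prop_negative=net.prop_negative,
        links_per_species=links / size,
        cluster_coefficient=bipartite_clustering(net),
        linkage_density=ld,
        weighted_connectance=weighted_connectance(ld, size),
        guild_counts={g: len(net.nodes_in_guild(g)) for g in net.guilds},
    )
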