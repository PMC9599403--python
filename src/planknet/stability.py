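"""Stability analysis: extinction robustness, vulnerability, subnetworks.

Robustness is the proportion of the original network's nodes that survive
after removing a fraction of one guild's nodes at random and cascading the
secondary extinction of any node left without edges.  Global efficiency is
the mean inverse shortest-path length over ordered node pairs (0 for
disconnected pairs, unweighted hops); a node's vulnerability is the relative
drop in global efficiency when it is deleted, and the network vulnerability
is the maximum over nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import SizeError, UndefinedMetricError, ValidationError
from .netinfer import BipartiteNetwork

__all__ = [
    "ExtinctionExperiment", "VulnerabilityReport", "RobustnessCurve",
    "simulate_extinctions", "robustness_curve", "curve_difference_test",
    "global_efficiency", "vulnerability", "extract_subnetwork",
]


@dataclass
class ExtinctionExperiment:
    target_guild: str
    removal_fraction: float
    n_trials: int
    robustness: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(self.robustness.mean())

    @property
    def sd(self) -> float:
        return float(self.robustness.std(ddof=1)) if self.n_trials > 1 else 0.0


@dataclass
class VulnerabilityReport:
    node_vulnerability: dict
    network_vulnerability: float
    global_efficiency: float


@dataclass
class RobustnessCurve:
    fractions: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    trials: np.ndarray          # shape (n_fractions, n_trials)
    slope: float
    intercept: float


def _surviving_fraction(graph: nx.Graph, removed: set) -> float:
    """Robustness after a fixed removal set: survivors keep >= 1 edge."""
    remaining = set(graph.nodes) - removed
    # iterate to a fixed point; under the >=1-edge rule one pass suffices,
    # the loop keeps the cascade rule explicit
    while True:
        extinct = {
            n for n in remaining
            if not any(nb in remaining for nb in graph.neighbors(n))
        }
        if not extinct:
            break
        remaining -= extinct
    return len(remaining) / graph.number_of_nodes()


def simulate_extinctions(net: BipartiteNetwork, target_guild: str,
                         f: float, n_trials: int = 100,
                         seed: int = 0) -> ExtinctionExperiment:
    """Random removal of ``round(f * guild size)`` nodes of one guild.

    ``target_guild`` may be a guild label or ``"both"`` (remove from all
    nodes).  Rounding is ties-to-even.
    """
    if not 0.0 < f <= 1.0:
        raise ValidationError(f"removal fraction must be in (0, 1], got {f}")
    g = net.graph
    if target_guild == "both":
        pool = list(g.nodes)
    else:
        pool = net.nodes_in_guild(target_guild)
        if not pool:
            raise ValidationError(f"guild {target_guild!r} absent from network")
    pool = sorted(pool)
    n_remove = round(f * len(pool))
    rng = np.random.default_rng(seed)
    if n_remove == 0:
        warnings.warn("removal fraction rounds to zero removals", stacklevel=2)
        return ExtinctionExperiment(
            target_guild, f, n_trials, np.ones(n_trials), seed
        )
    robustness = np.empty(n_trials)
    for t in range(n_trials):
        removed = set(rng.choice(pool, size=n_remove, replace=False))
        robustness[t] = _surviving_fraction(g, removed)
    return ExtinctionExperiment(target_guild, f, n_trials, robustness, seed)


def robustness_curve(net: BipartiteNetwork, target_guild: str,
                     fractions, n_trials: int = 100,
                     seed: int = 0) -> RobustnessCurve:
    """Mean robustness per removal fraction plus the least-squares slope."""
    fractions = np.asarray(list(fractions), dtype=float)
    if len(fractions) < 3:
        raise SizeError("need >= 3 fractions for a regression slope")
    if not (np.all(np.diff(fractions) > 0) and fractions[0] > 0
            and fractions[-1] <= 1):
        raise ValidationError("fractions must be strictly increasing in (0, 1]")
    seeds = np.random.SeedSequence(seed).generate_state(len(fractions))
    trials = np.empty((len(fractions), n_trials))
    for i, f in enumerate(fractions):
        exp = simulate_extinctions(net, target_guild, float(f),
                                   n_trials=n_trials, seed=int(seeds[i]))
        trials[i] = exp.robustness
    means = trials.mean(axis=1)
    sds = trials.std(axis=1, ddof=1) if n_trials > 1 else np.zeros_like(means)
    slope, intercept = np.polyfit(fractions, means, deg=1)
    return RobustnessCurve(fractions, means, sds, trials,
                           float(slope), float(intercept))


def curve_difference_test(trials_a: np.ndarray, trials_b: np.ndarray,
                          n_permutations: int = 999, seed: int = 0) -> dict:
    """Permutation test for a mean-robustness difference between two curves.

    Trial labels are permuted within each removal fraction; the statistic is
    the grand mean difference.  Two-sided p with add-one smoothing.
    """
    a = np.asarray(trials_a, dtype=float)
    b = np.asarray(trials_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("curves must share fractions and trial counts")
    rng = np.random.default_rng(seed)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b], axis=1)
    n = a.shape[1]
    exceed = 0
    for _ in range(n_permutations):
        perm = np.empty_like(pooled)
        for row in range(pooled.shape[0]):
            perm[row] = pooled[row, rng.permutation(pooled.shape[1])]
        stat = perm[:, :n].mean() - perm[:, n:].mean()
        if abs(stat) >= abs(observed):
            exceed += 1
    return {
        "statistic": float(observed),
        "p": (1 + exceed) / (1 + n_permutations),
        "n_permutations": n_permutations,
    }


def _graph_of(net) -> nx.Graph:
    return net.graph if isinstance(net, BipartiteNetwork) else net


def global_efficiency(net) -> float:
    """E = (1 / n(n-1)) * sum over ordered pairs of 1/d(i, j)."""
    g = _graph_of(net)
    n = g.number_of_nodes()
    if n < 2:
        raise SizeError("global efficiency needs >= 2 nodes")
    inv_sum = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if d > 0:
                inv_sum += 1.0 / d
    return inv_sum / (n * (n - 1))


def vulnerability(net) -> VulnerabilityReport:
    """Per-node relative efficiency loss (E - E_i) / E and its maximum."""
    g = _graph_of(net)
    if g.number_of_nodes() < 3:
        raise SizeError("vulnerability needs >= 3 nodes")
    e = global_efficiency(g)
    if e == 0.0:
        raise UndefinedMetricError("global efficiency is zero")
    node_vuln = {}
    for node in g.nodes:
        h = g.copy()
        h.remove_node(node)
        e_i = global_efficiency(h)
        node_vuln[node] = (e - e_i) / e
    return VulnerabilityReport(
        node_vulnerability=node_vuln,
        network_vulnerability=max(node_vuln.values()),
        global_efficiency=e,
    )


def extract_subnetwork(net: BipartiteNetwork, phyto_group: str,
                       phyto_guild: str = "phytoplankton") -> BipartiteNetwork:
    """Subnetwork of one phytoplankton taxon group plus its partners.

    Returns the induced subnetwork of the group's phytoplankton nodes and
    every zooplankton node sharing an edge with them.  The result carries a
    ``small_flag`` graph attribute when it has fewer than 20 nodes (and is
    simply empty when the group is absent).
    """
    g = net.graph
    selected = {
        n for n, d in g.nodes(data=True)
        if d.get("guild") == phyto_guild and d.get("taxon_group") == phyto_group
    }
    partners = {nb for n in selected for nb in g.neighbors(n)}
    sub = g.subgraph(selected | partners).copy()
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    out = BipartiteNetwork(sub)
    out.graph.graph["small_flag"] = sub.number_of_nodes() < 20
    return out
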