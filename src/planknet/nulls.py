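"""Degree-preserving null ensembles and empirical-vs-null tests.

Null networks are produced by repeated double-edge swaps (a-b, c-d ->
a-d, c-b) accepted only when both proposed edges are cross-guild and absent,
so the degree sequence, the guild bipartition, and the edge count are exact
invariants of every null network.  Rewired edges carry the attributes of
their first parent edge, conserving the edge-weight multiset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .netinfer import BipartiteNetwork

__all__ = ["NullEnsemble", "rewire", "null_metric_distribution",
           "compare_empirical_to_null"]


@dataclass
class NullEnsemble:
    """Per-metric null distributions for one empirical network."""

    n_networks: int
    empirical: dict
    null_values: dict          # metric -> np.ndarray of valid null values
    n_failed: dict             # metric -> count of failed evaluations
    seed: int


def rewire(net: BipartiteNetwork, n_swaps: int | None = None,
           seed: int | None = None) -> BipartiteNetwork:
    """One Maslov-Sneppen randomization of a bipartite network.

    ``n_swaps`` counts attempted swaps and defaults to 10x the edge count.
    """
    out = net.copy()
    g = out.graph
    edges = [(u, v) for u, v in g.edges()]
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges; returning network unchanged",
                      stacklevel=2)
        return out
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    rng = np.random.default_rng(seed)
    guild = {n: g.nodes[n]["guild"] for n in g.nodes}
    guild_a = min(set(guild.values()))
    # orient every edge (guild_a endpoint, other endpoint)
    oriented = [(u, v) if guild[u] == guild_a else (v, u) for u, v in edges]
    for _ in range(n_swaps):
        i, j = rng.choice(len(oriented), size=2, replace=False)
        a1, b1 = oriented[i]
        a2, b2 = oriented[j]
        if a1 == a2 or b1 == b2:
            continue
        if g.has_edge(a1, b2) or g.has_edge(a2, b1):
            continue
        attrs1 = dict(g.edges[a1, b1])
        attrs2 = dict(g.edges[a2, b2])
        g.remove_edge(a1, b1)
        g.remove_edge(a2, b2)
        g.add_edge(a1, b2, **attrs1)
        g.add_edge(a2, b1, **attrs2)
        oriented[i] = (a1, b2)
        oriented[j] = (a2, b1)
    return out


def null_metric_distribution(net: BipartiteNetwork, metric_fns: dict,
                             n_networks: int = 1000, seed: int = 0,
                             n_swaps: int | None = None) -> NullEnsemble:
    """Evaluate metrics on ``n_networks`` independently rewired networks.

    Metric failures on individual null networks are recorded and excluded.
    """
    empirical = {name: float(fn(net)) for name, fn in metric_fns.items()}
    values = {name: [] for name in metric_fns}
    failed = {name: 0 for name in metric_fns}
    seeds = np.random.SeedSequence(seed).spawn(n_networks)
    for ss in seeds:
        null_net = rewire(net, n_swaps=n_swaps,
                          seed=np.random.default_rng(ss))
        for name, fn in metric_fns.items():
            try:
                values[name].append(float(fn(null_net)))
            except Exception:
                failed[name] += 1
    return NullEnsemble(
        n_networks=n_networks,
        empirical=empirical,
        null_values={k: np.asarray(v, dtype=float) for k, v in values.items()},
        n_failed=failed,
        seed=seed,
    )


def compare_empirical_to_null(ensemble: NullEnsemble) -> dict:
    """One-sample t-test of each null vector against the empirical value.

    Conserved metrics (null sd = 0) are flagged degenerate instead of
    producing a t-statistic.
    """
    report = {}
    for name, null in ensemble.null_values.items():
        emp = ensemble.empirical[name]
        entry = {
            "empirical": emp,
            "null_mean": float(null.mean()) if null.size else float("nan"),
            "null_sd": float(null.std(ddof=1)) if null.size > 1 else 0.0,
            "n_valid": int(null.size),
            "n_failed": ensemble.n_failed[name],
        }
        if null.size < 2 or entry["null_sd"] == 0.0:
            entry.update(degenerate=True, t=None, p=None, significant=None)
        else:
            t, p = stats.ttest_1samp(null, popmean=emp)
            entry.update(degenerate=False, t=float(t), p=float(p),
                         significant=bool(p < 0.05))
        report[name] = entry
    return report
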