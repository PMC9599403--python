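"""Modules, hub classification, module eigenvalues, and environment links.

Modules are found by greedy modularity maximization on |r| edge weights.
Node roles follow the within-module degree z-score (Zi) and among-module
connectivity (Pi = 1 - sum_s (k_is / k_i)^2) with the four-way thresholds
Zi 2.5 and Pi 0.62; all non-peripheral nodes are "keystones".  A module's
eigenvalue series is the sign-oriented first principal component of its
members' z-scored abundance profiles.  Connectivity-environment coupling is
tested with a Mantel test between the Euclidean distance matrix of node
connectivities and that of node significance profiles (squared correlations
of abundance with each factor of a group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import SizeError, UndefinedMetricError, ValidationError
from .netinfer import BipartiteNetwork
from .tables_io import FACTOR_GROUPS, AbundanceTable, EnvironmentTable

__all__ = [
    "ModulePartition", "ZiPiRecord", "ModulePair", "ModuleEigen",
    "MantelResult", "detect_modules", "zi_pi", "classify_role",
    "module_eigenvalue", "module_env_correlation", "pair_preserved_modules",
    "mantel_connectivity_significance",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class ModulePartition:
    """node -> dense integer module id, plus provenance."""

    assignment: dict
    modularity: float
    algorithm: str = "greedy_modularity"
    seed: int = 0

    @property
    def module_ids(self) -> list:
        return sorted(set(self.assignment.values()))

    def members(self, module_id: int) -> list:
        return sorted(n for n, m in self.assignment.items() if m == module_id)

    @property
    def small_modules(self) -> list:
        """Modules with <= 5 nodes (flagged, not removed)."""
        return [m for m in self.module_ids if len(self.members(m)) <= 5]


@dataclass
class ZiPiRecord:
    node: str
    zi: float
    pi: float
    role: str

    @property
    def is_keystone(self) -> bool:
        return self.role != "peripheral"


@dataclass
class ModulePair:
    module_small: int
    module_big: int
    overlap: float
    paired: bool


@dataclass
class ModuleEigen:
    module_id: int
    series: pd.Series
    variance_explained: float


@dataclass
class MantelResult:
    statistic: float
    p: float
    n_species: int
    factor_group: str
    guild: str
    defined: bool = True


def detect_modules(net: BipartiteNetwork, seed: int = 0) -> ModulePartition:
    """Greedy modularity maximization on |r|-weighted edges."""
    if net.empty:
        raise ValidationError("cannot detect modules in an empty network")
    g = net.graph
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    communities = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    assignment = {n: i for i, c in enumerate(communities) for n in c}
    q = nx.community.modularity(
        g, [set(c) for c in communities], weight="weight"
    )
    return ModulePartition(assignment, float(q), seed=seed)


def classify_role(zi: float, pi: float) -> str:
    if zi > ZI_THRESHOLD:
        return "network hub" if pi > PI_THRESHOLD else "module hub"
    return "connector" if pi > PI_THRESHOLD else "peripheral"


def zi_pi(net: BipartiteNetwork, partition: ModulePartition) -> list:
    """Within-module degree z-score and among-module connectivity per node."""
    g = net.graph
    assignment = partition.assignment
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValidationError(f"partition does not cover nodes: {missing[:5]}")
    # within-module degree for every node
    k_own = {
        n: sum(1 for nb in g.neighbors(n) if assignment[nb] == assignment[n])
        for n in g.nodes
    }
    records = []
    for node in sorted(g.nodes):
        own = assignment[node]
        member_k = np.array([k_own[n] for n in g.nodes if assignment[n] == own],
                            dtype=float)
        sd = member_k.std()        # population sd; Zi = 0 when degenerate
        zi = 0.0 if sd == 0 else (k_own[node] - member_k.mean()) / sd
        k_i = g.degree(node)
        per_module = {}
        for nb in g.neighbors(node):
            per_module[assignment[nb]] = per_module.get(assignment[nb], 0) + 1
        pi = 1.0 - sum((k / k_i) ** 2 for k in per_module.values())
        records.append(ZiPiRecord(node, float(zi), float(pi),
                                  classify_role(zi, pi)))
    return records


def module_eigenvalue(members, abundance) -> ModuleEigen:
    """Sign-oriented, unit-variance first PC of member abundance profiles."""
    df = abundance.density if isinstance(abundance, AbundanceTable) else abundance
    members = list(members)
    missing = [m for m in members if m not in df.columns]
    if missing:
        raise ValidationError(f"module members missing from table: {missing}")
    x = df[members].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0           # constant member contributes zeros
    z = (x - mu) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = z @ vt[0]
    score_sd = scores.std()
    if score_sd > 0:
        scores = scores / score_sd
    mean_profile = z.mean(axis=1)
    if mean_profile.std() > 0 and np.corrcoef(scores, mean_profile)[0, 1] < 0:
        scores = -scores
    var_explained = float(s[0] ** 2 / (s ** 2).sum()) if s.size else 0.0
    return ModuleEigen(
        module_id=-1,
        series=pd.Series(scores, index=df.index, name="eigenvalue"),
        variance_explained=var_explained,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def module_env_correlation(eigen: ModuleEigen, env: EnvironmentTable) -> dict:
    """Pearson r, two-sided p, and significance stars per factor."""
    series = eigen.series
    shared = [s for s in series.index if s in set(env.sample_ids)]
    out = {}
    for factor in env.factor_names:
        x = series.loc[shared].to_numpy()
        y = env.factors.loc[shared, factor].to_numpy()
        if np.std(y) == 0 or np.std(x) == 0:
            out[factor] = {"r": float("nan"), "p": float("nan"),
                           "stars": "", "defined": False}
            continue
        r, p = stats.pearsonr(x, y)
        out[factor] = {"r": float(r), "p": float(p),
                       "stars": _stars(p), "defined": True}
    return out


def pair_preserved_modules(partition_small: ModulePartition,
                           partition_big: ModulePartition,
                           threshold: float = 0.5,
                           denominator: str = "min") -> list:
    """Greedy one-to-one pairing of modules sharing >= ``threshold`` of nodes.

    ``overlap(A, B) = |A & B| / min(|A|, |B|)`` by default (``denominator``
    may be "jaccard" for |A & B| / |A | B|).  Candidates are matched in
    descending overlap order, each module used at most once; the inclusive
    threshold means an overlap of exactly 0.5 pairs.
    """
    candidates = []
    for ms in partition_small.module_ids:
        a = set(partition_small.members(ms))
        for mb in partition_big.module_ids:
            b = set(partition_big.members(mb))
            inter = len(a & b)
            if denominator == "jaccard":
                denom = len(a | b)
            else:
                denom = min(len(a), len(b))
            overlap = inter / denom if denom else 0.0
            if overlap >= threshold:
                candidates.append((overlap, ms, mb))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_small, used_big = set(), set()
    pairs = []
    for overlap, ms, mb in candidates:
        selected = ms not in used_small and mb not in used_big
        if selected:
            used_small.add(ms)
            used_big.add(mb)
        pairs.append(ModulePair(ms, mb, float(overlap), selected))
    return pairs


def species_significance(abundance, env: EnvironmentTable, species,
                         factor_group: str) -> pd.DataFrame:
    """Squared Pearson correlation of each species with each group factor."""
    if factor_group not in FACTOR_GROUPS:
        raise ValidationError(
            f"unknown factor group {factor_group!r}; "
            f"expected one of {sorted(FACTOR_GROUPS)}"
        )
    df = abundance.density if isinstance(abundance, AbundanceTable) else abundance
    shared = [s for s in df.index if s in set(env.sample_ids)]
    factors = FACTOR_GROUPS[factor_group]
    rows = {}
    for sp in species:
        x = df.loc[shared, sp].to_numpy(dtype=float)
        rows[sp] = []
        for factor in factors:
            y = env.factors.loc[shared, factor].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows[sp].append(0.0)
            else:
                rows[sp].append(float(np.corrcoef(x, y)[0, 1] ** 2))
    return pd.DataFrame.from_dict(rows, orient="index", columns=factors)


def _mantel(d1: np.ndarray, d2: np.ndarray, n_permutations: int,
            rng: np.random.Generator):
    """One-sided (greater) Mantel test on two square distance matrices."""
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = d1[iu]
    v2 = d2[iu]
    if v1.std() == 0 or v2.std() == 0:
        return float("nan"), float("nan"), False
    observed = float(np.corrcoef(v1, v2)[0, 1])
    exceed = 0
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        perm = d2[np.ix_(idx, idx)][iu]
        if np.corrcoef(v1, perm)[0, 1] >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return observed, p, True


def mantel_connectivity_significance(net: BipartiteNetwork, abundance,
                                     env: EnvironmentTable, factor_group: str,
                                     guild: str, n_permutations: int = 999,
                                     seed: int = 0) -> MantelResult:
    """Mantel test: node connectivity vs environmental significance profiles.

    Both are turned into Euclidean distance matrices over the networked
    species of one guild; the statistic is the Pearson correlation of their
    off-diagonal entries, with a one-sided permutation p-value.
    """
    species = sorted(net.nodes_in_guild(guild))
    if len(species) < 5:
        raise SizeError(
            f"need >= 5 networked {guild} species, got {len(species)}"
        )
    degree = np.array([[net.graph.degree(s)] for s in species], dtype=float)
    signif = species_significance(abundance, env, species, factor_group)
    d1 = squareform(pdist(degree, metric="euclidean"))
    d2 = squareform(pdist(signif.to_numpy(), metric="euclidean"))
    rng = np.random.default_rng(seed)
    r, p, defined = _mantel(d1, d2, n_permutations, rng)
    return MantelResult(r, p, len(species), factor_group, guild, defined)
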