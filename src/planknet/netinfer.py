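"""Compositional correlation inference and bipartite network construction.

Correlations are estimated from log-ratio variances on pseudocount-adjusted
relative abundances: with t_ij = var(log(x_i / x_j)) across samples, basis
variances w solve the linear system sum_j t_ij = (d - 2) w_i + sum_j w_j
under the sparsity assumption, and the basis correlation is
r_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).  Strongly correlated pairs
(|r| above an exclusion threshold) are iteratively excluded from the system
and the solution is recomputed.  Significance comes from column-wise
permutation of the abundance table.  Edges are kept when |r| >= r_threshold
and p < p_threshold and both endpoints belong to different guilds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, SizeError
from .tables_io import AbundanceTable, combine_tables

__all__ = [
    "NetworkConfig", "CorrelationResult", "BipartiteNetwork",
    "sparcc_correlations", "permutation_pvalues",
    "build_bipartite_network", "build_zoozoo_network", "infer_network",
]


@dataclass
class NetworkConfig:
    """Thresholds and estimator settings for network construction."""

    r_threshold: float = 0.3
    p_threshold: float = 0.05
    n_permutations: int = 100
    sparcc_iterations: int = 10
    exclusion_threshold: float = 0.1
    #: None = data-adaptive: half the smallest positive density (0 if no
    #: zeros present). Densities are real-valued, so a fixed absolute
    #: pseudocount would turn zeros into extreme log outliers.
    pseudocount: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ConfigurationError("r_threshold must be in (0, 1)")
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.n_permutations < 20:
            raise ConfigurationError("n_permutations must be >= 20")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be positive")


@dataclass
class CorrelationResult:
    """Symmetric correlation (and optional p-value) matrices."""

    species: list
    r: pd.DataFrame
    p: pd.DataFrame | None = None

    def pair(self, a: str, b: str):
        pv = None if self.p is None else float(self.p.at[a, b])
        return float(self.r.at[a, b]), pv


@dataclass
class BipartiteNetwork:
    """A signed, weighted cross-guild network backed by a networkx graph.

    Node attributes: ``guild`` (bipartition label) and ``taxon_group``;
    edge attributes: ``r`` (signed), ``p``, ``weight`` (= |r|), ``sign``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def empty(self) -> bool:
        return self.graph.number_of_edges() == 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def guilds(self) -> list:
        return sorted({d["guild"] for _, d in self.graph.nodes(data=True)})

    def nodes_in_guild(self, guild: str) -> list:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("guild") == guild]

    def guild_of(self, node) -> str:
        return self.graph.nodes[node]["guild"]

    @property
    def prop_negative(self) -> float:
        if self.empty:
            return 0.0
        neg = sum(1 for _, _, d in self.graph.edges(data=True) if d["r"] < 0)
        return neg / self.n_edges

    def copy(self) -> "BipartiteNetwork":
        return BipartiteNetwork(self.graph.copy())

    # -- export ------------------------------------------------------------
    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_graphml(cls, path) -> "BipartiteNetwork":
        return cls(nx.read_graphml(path))

    def to_edge_tsv(self, path) -> None:
        rows = [
            {"source": u, "target": v, "r": d["r"], "p": d["p"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "r", "p"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Basis correlation estimation
# ---------------------------------------------------------------------------

def _logratio_variances(x: np.ndarray, pseudocount: float | None) -> np.ndarray:
    if pseudocount is None:
        has_zero = (x == 0).any()
        pseudocount = 0.5 * x[x > 0].min() if has_zero else 0.0
    frac = x + pseudocount
    frac = frac / frac.sum(axis=1, keepdims=True)
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(x: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """SparCC-style basis correlations for an (n_samples, d) matrix."""
    n, d = x.shape
    if d < 4:
        raise SizeError(f"need >= 4 species for basis-variance system, got {d}")
    if n < 4:
        raise SizeError(f"need >= 4 samples, got {n}")
    t = _logratio_variances(x, config.pseudocount)

    m = np.full((d, d), 1.0) + np.diag(np.full(d, float(d - 2)))
    t_eff = t.copy()
    excluded = np.zeros((d, d), dtype=bool)

    def _solve() -> np.ndarray:
        w = np.linalg.solve(m, t_eff.sum(axis=1))
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    rho = _solve()
    for _ in range(config.sparcc_iterations):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        masked[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= config.exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        t_eff[i, j] = 0.0
        t_eff[j, i] = 0.0
        try:
            rho = _solve()
        except np.linalg.LinAlgError:  # over-excluded system; keep last rho
            break
    return rho


def _drop_zero_species(df: pd.DataFrame) -> pd.DataFrame:
    zero = [c for c in df.columns if (df[c] == 0).all()]
    if zero:
        warnings.warn(
            f"dropping {len(zero)} all-zero species before correlation: "
            f"{zero[:5]}", stacklevel=3,
        )
        df = df.drop(columns=zero)
    return df


def _as_density(table) -> pd.DataFrame:
    return table.density if isinstance(table, AbundanceTable) else table


def sparcc_correlations(table, config: NetworkConfig | None = None
                        ) -> CorrelationResult:
    """Basis correlations for all species pairs of an abundance table."""
    config = config or NetworkConfig()
    df = _drop_zero_species(_as_density(table))
    rho = _basis_correlations(df.to_numpy(dtype=float), config)
    species = list(df.columns)
    r = pd.DataFrame(rho, index=species, columns=species)
    return CorrelationResult(species, r)


def permutation_pvalues(table, observed: CorrelationResult,
                        config: NetworkConfig | None = None
                        ) -> CorrelationResult:
    """Two-sided permutation p-values with add-one smoothing.

    Each permutation shuffles every species column independently, destroying
    all pairwise association while preserving marginals; p is the smoothed
    fraction of permutations whose |r| meets or exceeds the observed |r|.
    """
    config = config or NetworkConfig()
    df = _drop_zero_species(_as_density(table))[observed.species]
    x = df.to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    obs = np.abs(observed.r.to_numpy())
    exceed = np.zeros_like(obs)
    xp = np.empty_like(x)
    for _ in range(config.n_permutations):
        for j in range(x.shape[1]):
            xp[:, j] = x[rng.permutation(x.shape[0]), j]
        rho = _basis_correlations(xp, config)
        exceed += np.abs(rho) >= obs
    p = (1.0 + exceed) / (1.0 + config.n_permutations)
    np.fill_diagonal(p, 0.0)
    pdf = pd.DataFrame(p, index=observed.species, columns=observed.species)
    return CorrelationResult(observed.species, observed.r.copy(), pdf)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_bipartite_network(corr: CorrelationResult, guilds,
                            config: NetworkConfig | None = None,
                            taxon_group=None) -> BipartiteNetwork:
    """Keep cross-guild pairs with |r| >= r_threshold and p < p_threshold.

    Isolated species are excluded from the node set.  Within-guild pairs are
    never edges regardless of correlation.
    """
    config = config or NetworkConfig()
    if corr.p is None:
        raise ConfigurationError(
            "correlation result has no p-values; run permutation_pvalues first"
        )
    taxon_group = taxon_group or {}
    g = nx.Graph()
    species = corr.species
    rmat, pmat = corr.r, corr.p
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            if guilds[a] == guilds[b]:
                continue
            r = float(rmat.at[a, b])
            p = float(pmat.at[a, b])
            if abs(r) >= config.r_threshold and p < config.p_threshold:
                g.add_edge(a, b, r=r, p=p, weight=abs(r),
                           sign=1 if r >= 0 else -1)
    for n in g.nodes:
        g.nodes[n]["guild"] = guilds[n]
        g.nodes[n]["taxon_group"] = taxon_group.get(n, "")
    return BipartiteNetwork(g)


def infer_network(phyto: AbundanceTable, zoo: AbundanceTable,
                  config: NetworkConfig | None = None) -> BipartiteNetwork:
    """End-to-end phytoplankton x zooplankton network from two tables."""
    config = config or NetworkConfig()
    combined = combine_tables(phyto, zoo)
    corr = sparcc_correlations(combined, config)
    corr = permutation_pvalues(combined, corr, config)
    guilds = {s: combined.guild[s] for s in corr.species}
    taxon = {s: combined.taxon_group.get(s, "") for s in corr.species}
    return build_bipartite_network(corr, guilds, config, taxon)


def build_zoozoo_network(smaller: AbundanceTable, bigger: AbundanceTable,
                         config: NetworkConfig | None = None
                         ) -> BipartiteNetwork:
    """Bipartite network between the two zooplankton size fractions.

    Species occurring in both fractions are disambiguated with ``|S`` and
    ``|B`` suffixes, and the size fraction plays the role of the guild.
    """
    config = config or NetworkConfig()
    combined = combine_tables(smaller, bigger, suffixes=("|S", "|B"))
    corr = sparcc_correlations(combined, config)
    corr = permutation_pvalues(combined, corr, config)
    fractions = {
        s: ("smaller" if s.endswith("|S") else "bigger") for s in corr.species
    }
    taxon = {s: combined.taxon_group.get(s, "") for s in corr.species}
    return build_bipartite_network(corr, fractions, config, taxon)
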