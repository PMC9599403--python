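"""Synthetic plankton communities with known ground truth.

The generator draws per-species log-normal densities: a species' log density
is a base level plus a site-level shift, loadings on latent factors shared by
planted species pairs, optional coupling to environmental gradients, and
Gaussian noise.  Zeros are injected by independent Bernoulli thinning and an
optional per-sample closure rescales each row to a fixed total, producing the
compositional artifacts the correlation stage is designed to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SizeError
from .tables_io import (
    ENV_FACTORS,
    FACTOR_CLASS,
    AbundanceTable,
    EnvironmentTable,
    write_abundance_table,
    write_environment_table,
    write_sites,
    write_taxonomy,
)

#: Valid scopes for a planted association. The first three join a
#: phytoplankton species with a zooplankton species as measured in the named
#: size fraction(s); ``cross_fraction`` joins the smaller-fraction series of
#: one zooplankton species with the bigger-fraction series of another (or the
#: same) species.
EDGE_SCOPES = ("smaller", "bigger", "both", "cross_fraction")

_PHYTO_GROUPS = ("diatom", "dinoflagellate", "Ochrophyta")
_ZOO_GROUPS = ("Arthropoda", "Chaetognatha", "Tunicata", "Gastropoda")


def phyto_names(n: int) -> list:
    return [f"phyto_{i:03d}" for i in range(1, n + 1)]


def zoo_names(n: int) -> list:
    return [f"zoo_{i:03d}" for i in range(1, n + 1)]


@dataclass
class PlantedEdge:
    """A planted association between two species' latent log densities."""

    a: str
    b: str
    strength: float
    sign: int = 1
    scope: str = "both"

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigurationError(
                f"latent strength must be in [0, 1], got {self.strength}"
            )
        if self.sign not in (-1, 1):
            raise ConfigurationError(f"sign must be +1 or -1, got {self.sign}")
        if self.scope not in EDGE_SCOPES:
            raise ConfigurationError(f"unknown edge scope {self.scope!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth association structure for a synthetic community."""

    guild_sizes: dict = field(
        default_factory=lambda: {"phytoplankton": 20, "zooplankton": 16}
    )
    planted_edges: list = field(default_factory=list)
    env_coupled_species: dict = field(default_factory=dict)
    density_ratio: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.density_ratio <= 0:
            raise ConfigurationError("density_ratio must be positive")
        for g in ("phytoplankton", "zooplankton"):
            if self.guild_sizes.get(g, 0) < 1:
                raise ConfigurationError(f"guild_sizes[{g!r}] must be >= 1")
        phyto = set(phyto_names(self.guild_sizes["phytoplankton"]))
        zoo = set(zoo_names(self.guild_sizes["zooplankton"]))
        for e in self.planted_edges:
            if e.scope == "cross_fraction":
                if e.a not in zoo or e.b not in zoo:
                    raise ConfigurationError(
                        f"cross-fraction edge endpoints must be zooplankton: "
                        f"{e.a!r}-{e.b!r}"
                    )
            else:
                if e.a not in phyto or e.b not in zoo:
                    raise ConfigurationError(
                        f"cross-guild edge must join phytoplankton to "
                        f"zooplankton: {e.a!r}-{e.b!r}"
                    )
        for sp, (factor, coeff) in self.env_coupled_species.items():
            if sp not in phyto | zoo:
                raise ConfigurationError(f"unknown coupled species {sp!r}")
            if factor not in ENV_FACTORS:
                raise ConfigurationError(f"unknown factor name {factor!r}")
            if not -1.0 <= coeff <= 1.0:
                raise ConfigurationError("coupling coefficient must be in [-1, 1]")

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "guild_sizes": dict(self.guild_sizes),
            "planted_edges": [asdict(e) for e in self.planted_edges],
            "env_coupled_species": {
                sp: [factor, coeff]
                for sp, (factor, coeff) in self.env_coupled_species.items()
            },
            "density_ratio": self.density_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            guild_sizes=dict(d["guild_sizes"]),
            planted_edges=[PlantedEdge(**e) for e in d["planted_edges"]],
            env_coupled_species={
                sp: (f, c) for sp, (f, c) in d["env_coupled_species"].items()
            },
            density_ratio=d["density_ratio"],
        )


@dataclass
class GeneratorConfig:
    """Knobs of the community generator.

    ``association_scale`` and ``env_coupling_scale`` convert a latent strength
    or coupling coefficient into a loading on the log scale; ``noise_sd`` is
    the residual log-scale noise.
    """

    n_samples: int = 251
    n_sites: int = 12
    seed: int = 0
    zero_inflation: float = 0.0
    noise_sd: float = 0.5
    compositional_total: float | None = None
    association_scale: float = 2.0
    env_coupling_scale: float = 1.0
    site_shift_sd: float = 0.2
    base_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise SizeError("n_samples must be >= 4")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ConfigurationError("zero_inflation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.compositional_total is not None and self.compositional_total <= 0:
            raise ConfigurationError("compositional_total must be positive")


@dataclass
class CommunityTables:
    """The three generated density tables (one per net type)."""

    phyto: AbundanceTable
    zoo_smaller: AbundanceTable
    zoo_bigger: AbundanceTable

    def __iter__(self):
        yield from (self.phyto, self.zoo_smaller, self.zoo_bigger)


# ---------------------------------------------------------------------------
# Internal deterministic streams
# ---------------------------------------------------------------------------

def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _sites(config: GeneratorConfig):
    """Samples partitioned into contiguous site blocks."""
    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    labels = [f"site{(i * config.n_sites) // config.n_samples + 1:02d}"
              for i in range(config.n_samples)]
    return samples, labels


def _environment_matrix(config: GeneratorConfig) -> pd.DataFrame:
    """Raw factor matrix shared by community and environment generation."""
    rng = _rng(config, 1)
    samples, labels = _sites(config)
    n = config.n_samples
    site_idx = np.array([int(s[4:]) - 1 for s in labels], dtype=float)
    cols = {}
    for j, factor in enumerate(ENV_FACTORS):
        site_means = rng.normal(0.0, 1.0, size=config.n_sites)
        base = site_means[site_idx.astype(int)] + rng.normal(0.0, 0.6, size=n)
        if factor == "temperature":
            # latitudinal gradient: monotone trend across site blocks
            base = base + 2.0 * (site_idx / max(config.n_sites - 1, 1))
        cols[factor] = base
    # shift/scale to plausible ranges (cosmetic; correlations unaffected)
    scales = {
        "temperature": (22.0, 3.0), "salinity": (31.0, 1.5), "pH": (8.1, 0.15),
        "DO": (7.0, 1.0), "NO3N": (0.2, 0.08), "NO2N": (0.02, 0.008),
        "NH4N": (0.05, 0.02), "COD": (1.5, 0.5), "Zn": (20.0, 6.0),
        "Pb": (1.0, 0.3), "As": (2.0, 0.6), "Cu": (3.0, 1.0), "Hg": (0.05, 0.02),
    }
    out = {}
    for factor, v in cols.items():
        mu, sd = scales[factor]
        z = (v - v.mean()) / v.std()
        out[factor] = mu + sd * z
    return pd.DataFrame(out, index=samples)


def generate_environment(config: GeneratorConfig,
                         truth: SyntheticTruth) -> EnvironmentTable:
    """Generate the sample x factor table with site-structured gradients."""
    truth.validate()
    factors = _environment_matrix(config)
    samples, labels = _sites(config)
    return EnvironmentTable(
        factors, dict(FACTOR_CLASS), dict(zip(samples, labels))
    )


def generate_community(config: GeneratorConfig,
                       truth: SyntheticTruth) -> CommunityTables:
    """Generate the three density tables implied by a truth specification.

    Planted pairs share a standard-normal latent factor whose loading is
    ``strength * association_scale``; environment-coupled species load on the
    standardized factor at ``coeff * env_coupling_scale``; the smaller
    zooplankton fraction's log mean is raised by ``log(density_ratio)``.
    """
    truth.validate()
    n = config.n_samples
    samples, site_labels = _sites(config)
    site_idx = np.array([int(s[4:]) - 1 for s in site_labels])

    p_names = phyto_names(truth.guild_sizes["phytoplankton"])
    z_names = zoo_names(truth.guild_sizes["zooplankton"])

    env = _environment_matrix(config)
    env_z = (env - env.mean()) / env.std()

    rng = _rng(config, 2)
    # latent factor per planted edge
    edge_factors = {id(e): rng.standard_normal(n) for e in truth.planted_edges}

    # series keys: ("phyto", sp), ("zoo_smaller", sp), ("zoo_bigger", sp)
    # A zooplankton species shares its base level and site shifts across the
    # two size fractions (one species, two measurements); only the noise and
    # planted loadings are fraction-specific.
    levels = {}
    for sp in p_names + z_names:
        base = rng.normal(0.0, config.base_log_sd)
        site_shift = rng.normal(0.0, config.site_shift_sd, size=config.n_sites)
        levels[sp] = base + site_shift[site_idx]

    keys = ([("phyto", s) for s in p_names]
            + [("zoo_smaller", s) for s in z_names]
            + [("zoo_bigger", s) for s in z_names])
    log_density = {}
    for kind, sp in keys:
        series = levels[sp] + rng.normal(0.0, config.noise_sd, size=n)
        if kind == "zoo_smaller":
            series = series + np.log(truth.density_ratio)
        if sp in truth.env_coupled_species:
            factor, coeff = truth.env_coupled_species[sp]
            series = series + coeff * config.env_coupling_scale * \
                env_z[factor].to_numpy()
        log_density[(kind, sp)] = series

    for e in truth.planted_edges:
        lam = e.strength * config.association_scale
        z = edge_factors[id(e)]
        if e.scope == "cross_fraction":
            log_density[("zoo_smaller", e.a)] = \
                log_density[("zoo_smaller", e.a)] + lam * z
            log_density[("zoo_bigger", e.b)] = \
                log_density[("zoo_bigger", e.b)] + e.sign * lam * z
        else:
            fractions = (("smaller", "bigger") if e.scope == "both"
                         else (e.scope,))
            log_density[("phyto", e.a)] = log_density[("phyto", e.a)] + lam * z
            for frac in fractions:
                key = (f"zoo_{frac}", e.b)
                log_density[key] = log_density[key] + e.sign * lam * z

    def _table(kind: str, names: list, guild: str, frac: str | None,
               groups: tuple) -> AbundanceTable:
        mat = np.exp(np.column_stack([log_density[(kind, s)] for s in names]))
        if config.zero_inflation > 0:
            mask = rng.random(mat.shape) < config.zero_inflation
            mat = np.where(mask, 0.0, mat)
        if config.compositional_total is not None:
            totals = mat.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            mat = mat / totals * config.compositional_total
        df = pd.DataFrame(mat, index=samples, columns=names)
        return AbundanceTable(
            df,
            guild={s: guild for s in names},
            size_fraction={} if frac is None else {s: frac for s in names},
            taxon_group={s: groups[i % len(groups)]
                         for i, s in enumerate(names)},
            site=dict(zip(samples, site_labels)),
        )

    phyto = _table("phyto", p_names, "phytoplankton", None, _PHYTO_GROUPS)
    zoo_s = _table("zoo_smaller", z_names, "zooplankton", "smaller", _ZOO_GROUPS)
    zoo_b = _table("zoo_bigger", z_names, "zooplankton", "bigger", _ZOO_GROUPS)
    return CommunityTables(phyto, zoo_s, zoo_b)


def write_fixture(tables: CommunityTables, env: EnvironmentTable,
                  truth: SyntheticTruth, directory) -> dict:
    """Write all fixture files to ``directory`` and return a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "phyto.tsv": tables.phyto,
        "zoo_smaller.tsv": tables.zoo_smaller,
        "zoo_bigger.tsv": tables.zoo_bigger,
    }
    manifest = {"files": {}}
    for name, table in files.items():
        write_abundance_table(table, directory / name)
        manifest["files"][name] = {
            "rows": table.n_samples, "columns": table.n_species,
        }
    write_taxonomy(list(tables), directory / "taxonomy.tsv")
    manifest["files"]["taxonomy.tsv"] = {
        "rows": len({s for t in tables for s in t.species_ids}),
        "columns": 3,
    }
    write_environment_table(env, directory / "environment.tsv")
    manifest["files"]["environment.tsv"] = {
        "rows": len(env.sample_ids), "columns": len(env.factor_names),
    }
    write_sites(tables.phyto.site, directory / "samples.tsv")
    manifest["files"]["samples.tsv"] = {
        "rows": len(tables.phyto.site), "columns": 1,
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
    manifest["files"]["truth.json"] = {
        "rows": len(truth.planted_edges), "columns": 4,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))


def demo_truth(n_phyto: int = 20, n_zoo: int = 16,
               n_edges_smaller: int = 8, n_edges_bigger: int = 3,
               strength: float = 0.9, density_ratio: float = 2.5,
               env_couplings: dict | None = None) -> SyntheticTruth:
    """A small default truth: more planted associations in the smaller
    fraction so the smaller-fraction network comes out larger."""
    p = phyto_names(n_phyto)
    z = zoo_names(n_zoo)
    edges = []
    for i in range(n_edges_smaller):
        sign = -1 if i % 4 == 3 else 1
        edges.append(PlantedEdge(p[i % n_phyto], z[i % n_zoo],
                                 strength, sign, "smaller"))
    for i in range(n_edges_bigger):
        edges.append(PlantedEdge(p[(i + n_edges_smaller) % n_phyto],
                                 z[(i + n_edges_smaller) % n_zoo],
                                 strength, 1, "bigger"))
    couplings = env_couplings if env_couplings is not None else {
        z[0]: ("temperature", 0.8),
        p[0]: ("pH", 0.7),
    }
    return SyntheticTruth(
        guild_sizes={"phytoplankton": n_phyto, "zooplankton": n_zoo},
        planted_edges=edges,
        env_coupled_species=couplings,
        density_ratio=density_ratio,
    )
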