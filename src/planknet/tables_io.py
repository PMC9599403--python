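"""Data model and I/O for abundance, taxonomy, and environment tables.

Tables are plain TSV/CSV: abundance files have one header row of species
names and a first column of sample identifiers; the taxonomy file maps each
species to its guild, size fraction, and taxon group; the environment file
holds one named factor per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import EmptyIntersectionError, SizeError, ValidationError

GUILDS = ("phytoplankton", "zooplankton")
SIZE_FRACTIONS = ("smaller", "bigger")

#: Canonical environmental factor names, in column order.
ENV_FACTORS = [
    "temperature", "salinity", "pH", "DO",
    "NO3N", "NO2N", "NH4N", "COD",
    "Zn", "Pb", "As", "Cu", "Hg",
]

#: Broad factor classes (water chemistry / nitrogen / heavy metals).
FACTOR_CLASS = {
    "temperature": "water", "salinity": "water", "pH": "water",
    "DO": "water", "COD": "water",
    "NO3N": "N", "NO2N": "N", "NH4N": "N",
    "Zn": "metal", "Pb": "metal", "As": "metal", "Cu": "metal", "Hg": "metal",
}

#: Factor groupings used by the connectivity-vs-significance Mantel tests.
FACTOR_GROUPS = {
    "temperature": ["temperature"],
    "salinity": ["salinity"],
    "N": ["NO3N", "NO2N", "NH4N"],
    "pH": ["pH"],
    "metal": ["Zn", "Pb", "As", "Cu", "Hg"],
}


def _norm_name(name: str) -> str:
    """Normalize a species name for matching: strip and casefold."""
    return " ".join(str(name).split()).casefold()


@dataclass
class AbundanceTable:
    """Samples x species density matrix with guild/fraction/taxon annotations.

    Parameters
    ----------
    density : pandas.DataFrame
        Rows are samples, columns are species, values are densities (ind/L).
    guild : mapping species -> {"phytoplankton", "zooplankton"}.
    size_fraction : mapping zooplankton species -> {"smaller", "bigger"}.
    taxon_group : mapping species -> taxon group label.
    site : mapping sample -> site label.
    """

    density: pd.DataFrame
    guild: dict = field(default_factory=dict)
    size_fraction: dict = field(default_factory=dict)
    taxon_group: dict = field(default_factory=dict)
    site: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        df = self.density
        if df.index.duplicated().any():
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate species ids: {dupes}")
        neg = df.lt(0)
        if neg.any().any():
            col = neg.any(axis=0).idxmax()
            row = neg[col].idxmax()
            raise ValidationError(
                f"negative density at sample={row!r}, species={col!r}: "
                f"{df.at[row, col]}"
            )
        missing = [s for s in df.columns if s not in self.guild]
        if missing:
            raise ValidationError(f"species without guild assignment: {missing}")
        bad_guild = {s: g for s, g in self.guild.items() if g not in GUILDS}
        if bad_guild:
            raise ValidationError(f"unknown guild labels: {bad_guild}")
        no_frac = [
            s for s in df.columns
            if self.guild.get(s) == "zooplankton" and s not in self.size_fraction
        ]
        if no_frac:
            raise ValidationError(
                f"zooplankton species without size fraction: {no_frac}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.density.index)

    @property
    def species_ids(self) -> list:
        return list(self.density.columns)

    @property
    def n_samples(self) -> int:
        return len(self.density.index)

    @property
    def n_species(self) -> int:
        return len(self.density.columns)

    def species_of_guild(self, guild: str) -> list:
        return [s for s in self.density.columns if self.guild.get(s) == guild]

    def subset_species(self, species) -> "AbundanceTable":
        species = list(species)
        return AbundanceTable(
            density=self.density[species].copy(),
            guild={s: self.guild[s] for s in species},
            size_fraction={s: self.size_fraction[s]
                           for s in species if s in self.size_fraction},
            taxon_group={s: self.taxon_group[s]
                         for s in species if s in self.taxon_group},
            site=dict(self.site),
        )

    def subset_samples(self, samples) -> "AbundanceTable":
        samples = list(samples)
        return AbundanceTable(
            density=self.density.loc[samples].copy(),
            guild=dict(self.guild),
            size_fraction=dict(self.size_fraction),
            taxon_group=dict(self.taxon_group),
            site={s: self.site[s] for s in samples if s in self.site},
        )


@dataclass
class EnvironmentTable:
    """Samples x environmental-factor matrix.

    ``factor_class`` maps each factor to its broad class (water/N/metal);
    ``site`` maps samples to site labels (used by per-site imputation).
    """

    factors: pd.DataFrame
    factor_class: dict = field(default_factory=lambda: dict(FACTOR_CLASS))
    site: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.factors.index.duplicated().any():
            raise ValidationError("duplicate sample ids in environment table")

    @property
    def sample_ids(self) -> list:
        return list(self.factors.index)

    @property
    def factor_names(self) -> list:
        return list(self.factors.columns)

    def impute_missing(self) -> "EnvironmentTable":
        """Fill missing values with per-site medians (global median fallback)."""
        df = self.factors.copy()
        if self.site:
            groups = pd.Series({s: self.site.get(s, "_na") for s in df.index})
            df = df.groupby(groups.reindex(df.index)).transform(
                lambda col: col.fillna(col.median())
            )
        df = df.fillna(df.median())
        return EnvironmentTable(df, dict(self.factor_class), dict(self.site))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    """Read a delimited table, auto-detecting tab vs comma."""
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy table indexed by species.

    Expected columns: ``guild``, ``size_fraction``, ``taxon_group``.
    """
    tax = _read_table(path)
    required = {"guild"}
    missing = required - set(tax.columns)
    if missing:
        raise ValidationError(f"taxonomy file missing columns: {sorted(missing)}")
    return tax


def read_sites(path) -> dict:
    """Read a two-column (sample, site) table into a mapping."""
    df = _read_table(path)
    return {str(k): str(v) for k, v in df.iloc[:, 0].items()}


def read_abundance_table(path, taxonomy_path, sites_path=None) -> AbundanceTable:
    """Read and validate an abundance table against a taxonomy file.

    Raises :class:`ValidationError` for negative densities or species absent
    from the taxonomy (listing the offenders).
    """
    df = _read_table(path)
    df = df.apply(pd.to_numeric)
    tax = read_taxonomy(taxonomy_path)
    gap = [s for s in df.columns if s not in tax.index]
    if gap:
        raise ValidationError(f"species missing from taxonomy: {gap}")
    guild = {s: str(tax.at[s, "guild"]) for s in df.columns}
    size_fraction = {}
    taxon_group = {}
    for s in df.columns:
        if "size_fraction" in tax.columns:
            v = tax.at[s, "size_fraction"]
            if isinstance(v, str) and v:
                size_fraction[s] = v
        if "taxon_group" in tax.columns:
            v = tax.at[s, "taxon_group"]
            if isinstance(v, str) and v:
                taxon_group[s] = v
    site = read_sites(sites_path) if sites_path else {}
    return AbundanceTable(df, guild, size_fraction, taxon_group, site)


def read_environment_table(path, sites_path=None) -> EnvironmentTable:
    df = _read_table(path).apply(pd.to_numeric)
    site = read_sites(sites_path) if sites_path else {}
    fclass = {f: FACTOR_CLASS.get(f, "other") for f in df.columns}
    return EnvironmentTable(df, fclass, site)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.density.to_csv(path, sep="\t", index_label="sample_id")


def write_taxonomy(tables, path) -> None:
    """Write one merged taxonomy TSV for any number of abundance tables."""
    rows = {}
    for t in tables:
        for s in t.species_ids:
            rows[s] = {
                "guild": t.guild.get(s, ""),
                "size_fraction": t.size_fraction.get(s, ""),
                "taxon_group": t.taxon_group.get(s, ""),
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    df.to_csv(path, sep="\t")


def write_environment_table(env: EnvironmentTable, path) -> None:
    env.factors.to_csv(path, sep="\t", index_label="sample_id")


def write_sites(site: Mapping, path) -> None:
    df = pd.DataFrame({"site": pd.Series(dict(site))})
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def intersect_size_fractions(smaller: AbundanceTable, bigger: AbundanceTable):
    """Keep only zooplankton species caught in both size fractions.

    Returns the two filtered tables plus a report with counts of species
    exclusive to each net and the shared count.  Matching is by exact name
    after whitespace/case normalization.
    """
    zoo_s = smaller.species_of_guild("zooplankton")
    zoo_b = bigger.species_of_guild("zooplankton")
    norm_s = {_norm_name(s): s for s in zoo_s}
    norm_b = {_norm_name(s): s for s in zoo_b}
    shared_keys = sorted(set(norm_s) & set(norm_b))
    report = {
        "smaller_total": len(zoo_s),
        "bigger_total": len(zoo_b),
        "smaller_only": len(zoo_s) - len(shared_keys),
        "bigger_only": len(zoo_b) - len(shared_keys),
        "shared": len(shared_keys),
    }
    if not shared_keys:
        raise EmptyIntersectionError(
            "no zooplankton species shared between size fractions"
        )

    def _filter(table: AbundanceTable, keep_zoo: set) -> AbundanceTable:
        keep = [
            s for s in table.species_ids
            if table.guild.get(s) != "zooplankton" or s in keep_zoo
        ]
        return table.subset_species(keep)

    out_s = _filter(smaller, {norm_s[k] for k in shared_keys})
    out_b = _filter(bigger, {norm_b[k] for k in shared_keys})
    return out_s, out_b, report


def align_samples(abundance: AbundanceTable, env: EnvironmentTable):
    """Restrict both tables to their shared samples, in identical order."""
    shared = [s for s in abundance.sample_ids if s in set(env.sample_ids)]
    if len(shared) < 4:
        raise SizeError(
            f"only {len(shared)} shared samples between abundance and "
            "environment tables; need >= 4"
        )
    report = {
        "shared": len(shared),
        "abundance_dropped": abundance.n_samples - len(shared),
        "environment_dropped": len(env.sample_ids) - len(shared),
    }
    ab = abundance.subset_samples(shared)
    ev = EnvironmentTable(
        env.factors.loc[shared].copy(), dict(env.factor_class),
        {s: env.site[s] for s in shared if s in env.site},
    )
    return ab, ev, report


def combine_tables(a: AbundanceTable, b: AbundanceTable,
                   suffixes=(None, None)) -> AbundanceTable:
    """Concatenate two tables column-wise on their shared samples.

    Optional suffixes disambiguate species occurring in both tables (as when
    combining the two zooplankton size fractions).
    """
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if len(shared) < 4:
        raise SizeError("fewer than 4 shared samples when combining tables")

    def _suffixed(t: AbundanceTable, suffix):
        if suffix is None:
            return t.subset_samples(shared)
        ren = {s: f"{s}{suffix}" for s in t.species_ids}
        return AbundanceTable(
            t.density.loc[shared].rename(columns=ren),
            {ren[s]: g for s, g in t.guild.items() if s in ren},
            {ren[s]: f for s, f in t.size_fraction.items() if s in ren},
            {ren[s]: g for s, g in t.taxon_group.items() if s in ren},
            {s: t.site[s] for s in shared if s in t.site},
        )

    ta, tb = _suffixed(a, suffixes[0]), _suffixed(b, suffixes[1])
    clash = set(ta.species_ids) & set(tb.species_ids)
    if clash:
        raise ValidationError(
            f"species present in both tables (use suffixes): {sorted(clash)[:5]}"
        )
    density = pd.concat([ta.density, tb.density], axis=1)
    return AbundanceTable(
        density,
        {**ta.guild, **tb.guild},
        {**ta.size_fraction, **tb.size_fraction},
        {**ta.taxon_group, **tb.taxon_group},
        {**ta.site, **tb.site},
    )
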