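"""Input tables, trait preprocessing and species-pool construction.

The framework compares species at three nested levels of organisation:
the regional species list, the habitat-specific species pool (the subset
of the regional list able to colonise the focal habitat type), and the
locally observed community.  Regional species absent from the habitat
pool are *environmentally excluded*; pool members absent from the focal
community form the *dark diversity* (biotically excluded candidates).

All tables are thin wrappers around pandas objects with the validation
logic the modelling stages rely on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVEL_ENV_EXCLUDED = "environmentally_excluded"
LEVEL_DARK = "dark_diversity"
LEVEL_OBSERVED = "observed"

CONTINUOUS = "continuous"
ORDINAL = "ordinal"


class TableError(ValueError):
    """Hard error raised for malformed or degenerate input tables."""


@dataclass
class ValidationReport:
    """Collected warnings from reading and cross-checking input tables."""

    duplicate_rows: dict = field(default_factory=dict)       # table -> count
    unknown_species: dict = field(default_factory=dict)      # table -> sorted list
    incomplete_traits: list = field(default_factory=list)    # species with missing traits
    messages: list = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return (
            not any(self.duplicate_rows.values())
            and not any(self.unknown_species.values())
            and not self.incomplete_traits
            and not self.messages
        )

    def warn(self, msg: str) -> None:
        self.messages.append(msg)
        logger.warning(msg)


@dataclass
class TraitTable:
    """Species-by-trait values plus trait metadata.

    Parameters
    ----------
    values
        DataFrame indexed by species_id with one numeric column per trait.
        May contain NaN; species with any missing modelled trait are kept
        in the table but excluded from ``modeling_species``.
    kinds
        trait name -> ``"continuous"`` or ``"ordinal"``.
    log_traits
        Traits to natural-log transform before range standardisation
        (used for strongly right-skewed traits such as height, SLA and
        seed weight).
    standardized
        True once every modelled trait has been mapped to [0, 1].
    scaling
        Per-trait (min, max) of the post-log values over the modelling
        set; stored so the identical affine map can be applied to
        colonists supplied later.
    """

    values: pd.DataFrame
    kinds: dict
    log_traits: frozenset = frozenset()
    standardized: bool = False
    scaling: pd.DataFrame | None = None
    modeling_species: pd.Index | None = None
    incomplete_species: tuple = ()

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate species_id in trait table: {dupes}")
        unknown = set(self.kinds) - set(self.values.columns)
        if unknown:
            raise TableError(f"trait kinds declared for unknown traits: {sorted(unknown)}")

    @property
    def traits(self) -> list:
        return list(self.values.columns)

    @property
    def species(self) -> pd.Index:
        return self.values.index

    def complete_species(self) -> pd.Index:
        """Species with no missing value on any modelled trait."""
        return self.values.index[self.values.notna().all(axis=1)]

    def subset(self, species) -> pd.DataFrame:
        return self.values.loc[list(species)]


def preprocess_traits(
    raw: TraitTable,
    log_traits=None,
    modeling_species=None,
) -> TraitTable:
    """Log-transform flagged traits and rescale every trait to [0, 1].

    The min/max for the rescaling is computed over ``modeling_species``
    (default: all species with complete traits); the same affine map is
    then applied to every species in the table, so colonists outside the
    modelled trait range may legitimately fall outside [0, 1] (logged,
    not an error).  Ordinal traits (e.g. Ellenberg indicator values) are
    rescaled with the same rule.
    """
    log_traits = frozenset(log_traits if log_traits is not None else raw.log_traits)
    values = raw.values.astype(float).copy()

    unknown = log_traits - set(values.columns)
    if unknown:
        raise TableError(f"log flag for unknown traits: {sorted(unknown)}")
    for trait in sorted(log_traits):
        col = values[trait]
        if (col <= 0).any():
            bad = values.index[col <= 0].tolist()
            raise TableError(
                f"trait {trait!r} flagged for log transform has non-positive values for {bad}"
            )
        values[trait] = np.log(col)

    complete = values.index[values.notna().all(axis=1)]
    if modeling_species is not None:
        modeling = complete.intersection(pd.Index(modeling_species))
    else:
        modeling = complete
    if len(modeling) == 0:
        raise TableError("no species with complete traits in the modeling set")
    incomplete = tuple(values.index.difference(complete))

    ref = values.loc[modeling]
    lo, hi = ref.min(), ref.max()
    span = hi - lo
    zero = span[span == 0]
    if len(zero):
        raise TableError(f"zero range over the modeling set for trait(s): {list(zero.index)}")

    scaled = (values - lo) / span
    out_of_range = scaled.drop(index=modeling, errors="ignore")
    oob = out_of_range[(out_of_range < 0) | (out_of_range > 1)].stack()
    if len(oob):
        logger.info(
            "%d trait value(s) outside [0, 1] after standardization (species outside "
            "the modeling range): %s",
            len(oob),
            sorted({s for s, _ in oob.index}),
        )

    scaling = pd.DataFrame({"min": lo, "max": hi})
    return TraitTable(
        values=scaled,
        kinds=dict(raw.kinds),
        log_traits=log_traits,
        standardized=True,
        scaling=scaling,
        modeling_species=modeling,
        incomplete_species=incomplete,
    )


@dataclass
class OccurrenceTable:
    """Long-format site occupancy records for one habitat type."""

    records: pd.DataFrame  # columns: site_id, species_id

    def __post_init__(self) -> None:
        missing = {"site_id", "species_id"} - set(self.records.columns)
        if missing:
            raise TableError(f"occurrence table missing columns: {sorted(missing)}")

    @property
    def sites(self) -> pd.Index:
        return pd.Index(sorted(self.records["site_id"].unique()))

    def species_at(self, site_id) -> set:
        rec = self.records
        return set(rec.loc[rec["site_id"] == site_id, "species_id"])

    def site_counts(self) -> pd.Series:
        """Number of distinct sites each species occurs in."""
        return self.records.groupby("species_id")["site_id"].nunique()


@dataclass
class PoolAssignment:
    """Per-species membership level relative to one focal community.

    Levels partition the regional list: environmentally excluded species
    are regional species outside the habitat pool; pool members absent
    from the focal community are the dark diversity; the rest are
    observed.  ``dark ∪ observed = habitat pool`` by construction.
    """

    table: pd.DataFrame  # index species_id; columns level, in_regional, in_habitat_pool
    focal_site: str | None = None

    @property
    def species(self) -> pd.Index:
        return self.table.index

    @property
    def pool_species(self) -> pd.Index:
        return self.table.index[self.table["in_habitat_pool"]]

    @property
    def observed_species(self) -> pd.Index:
        return self.table.index[self.table["level"] == LEVEL_OBSERVED]

    @property
    def dark_species(self) -> pd.Index:
        return self.table.index[self.table["level"] == LEVEL_DARK]

    @property
    def excluded_species(self) -> pd.Index:
        return self.table.index[self.table["level"] == LEVEL_ENV_EXCLUDED]

    def counts(self) -> dict:
        return self.table["level"].value_counts().to_dict()


def build_habitat_pool(
    occ: OccurrenceTable,
    regional,
    focal_site,
    min_sites: int = 2,
) -> PoolAssignment:
    """Derive the habitat-specific pool and dark diversity for one focal site.

    A regional species enters the habitat pool when it occurs in at least
    ``min_sites`` sites of the habitat type (the default of 2 drops
    single-site records, guarding against misidentifications and habitat
    vagrants).  Species observed at the focal site itself are always pool
    members — they demonstrably occur there — which keeps observed ⊆ pool.
    Occurrence records for species absent from the regional list are
    ignored (they may be unable to disperse to the focal site).
    """
    regional = pd.Index(sorted(set(regional)))
    if focal_site not in set(occ.records["site_id"]):
        raise TableError(f"focal site {focal_site!r} not present in occurrence table")

    counts = occ.site_counts()
    frequent = set(counts.index[counts >= min_sites])
    focal_species = occ.species_at(focal_site)
    pool = (frequent | focal_species) & set(regional)
    if not pool:
        raise TableError("habitat-specific pool is empty")

    observed = focal_species & pool
    level = pd.Series(LEVEL_ENV_EXCLUDED, index=regional, name="level")
    level.loc[sorted(pool - observed)] = LEVEL_DARK
    level.loc[sorted(observed)] = LEVEL_OBSERVED
    table = pd.DataFrame(
        {
            "level": level,
            "in_regional": True,
            "in_habitat_pool": level != LEVEL_ENV_EXCLUDED,
        }
    )
    return PoolAssignment(table=table, focal_site=focal_site)


@dataclass
class CommunityTable:
    """Plot-level abundance records (counts of individuals)."""

    records: pd.DataFrame  # columns: plot_id, site_id, species_id, count

    REQUIRED = ("plot_id", "site_id", "species_id", "count")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise TableError(f"community table missing columns: {sorted(missing)}")
        if (self.records["count"] < 0).any():
            raise TableError("negative counts in community table")

    @property
    def plots(self) -> pd.Index:
        return pd.Index(sorted(self.records["plot_id"].unique()))

    @property
    def species(self) -> pd.Index:
        return pd.Index(sorted(self.records["species_id"].unique()))

    def site_of_plot(self) -> pd.Series:
        return self.records.drop_duplicates("plot_id").set_index("plot_id")["site_id"]

    def plot_counts(self, plot_id) -> pd.Series:
        rec = self.records
        sub = rec.loc[rec["plot_id"] == plot_id]
        counts = sub.set_index("species_id")["count"].sort_index()
        return counts[counts > 0]

    def relative_abundances(self, plot_id) -> pd.Series:
        counts = self.plot_counts(plot_id)
        total = counts.sum()
        if total <= 0:
            raise TableError(f"plot {plot_id!r} has zero total count")
        return counts / total


@dataclass
class ColonistTable:
    """Seed-addition records: seeds sown and plants recorded in year three."""

    records: pd.DataFrame  # species_id, site_id, plot_id, seeds_added, plants_year3[, is_native]

    REQUIRED = ("species_id", "site_id", "plot_id", "seeds_added", "plants_year3")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise TableError(f"colonist table missing columns: {sorted(missing)}")
        if (self.records["seeds_added"] <= 0).any():
            raise TableError("seeds_added must be positive")
        if "is_native" not in self.records.columns:
            self.records = self.records.assign(is_native=True)
        over = self.records["plants_year3"] > self.records["seeds_added"]
        if over.any():
            logger.warning(
                "plants_year3 exceeds seeds_added for %d row(s) (recruitment or clonal "
                "spread); kept as-is",
                int(over.sum()),
            )

    @property
    def species(self) -> pd.Index:
        return pd.Index(sorted(self.records["species_id"].unique()))

    def native_species(self) -> pd.Index:
        nat = self.records.groupby("species_id")["is_native"].first()
        return pd.Index(sorted(nat.index[nat.astype(bool)]))


def actual_establishment(colonists: ColonistTable) -> pd.Series:
    """Observed establishment: per species, the mean over its plots of
    plants in year three divided by seeds added."""
    rec = colonists.records
    prop = rec["plants_year3"] / rec["seeds_added"]
    out = prop.groupby(rec["species_id"]).mean().sort_index()
    out.name = "actual_establishment"
    return out


# ---------------------------------------------------------------------------
# CSV reading

_SCHEMAS = {
    "regional": ["species_id"],
    "occurrences": ["site_id", "species_id"],
    "community": ["plot_id", "site_id", "species_id", "count"],
    "colonists": ["species_id", "site_id", "plot_id", "seeds_added", "plants_year3"],
}


def _read_csv(path, required_cols) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed delimiter / encoding
        raise TableError(f"cannot parse {path}: {exc}") from exc
    missing = set(required_cols) - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def read_tables(
    traits_path,
    regional_path,
    occurrences_path,
    community_path=None,
    colonists_path=None,
    trait_kinds=None,
    log_traits=(),
):
    """Read and cross-validate the CSV inputs.

    Returns ``(traits, regional_index, occurrences, community, colonists,
    report)``; ``community``/``colonists`` are None when their paths are.
    Duplicate rows are dropped with a warning; species that cannot be
    resolved against the regional list are reported, not silently used.
    """
    report = ValidationReport()

    tdf = _read_csv(traits_path, ["species_id"]).set_index("species_id")
    if tdf.index.has_duplicates:
        n = int(tdf.index.duplicated().sum())
        report.duplicate_rows["traits"] = n
        report.warn(f"traits: dropped {n} duplicate species row(s)")
        tdf = tdf[~tdf.index.duplicated()]
    kinds = dict(trait_kinds) if trait_kinds else {c: CONTINUOUS for c in tdf.columns}
    traits = TraitTable(values=tdf.astype(float), kinds=kinds, log_traits=frozenset(log_traits))
    incomplete = tdf.index[tdf.isna().any(axis=1)].tolist()
    if incomplete:
        report.incomplete_traits = sorted(incomplete)
        report.warn(
            f"traits: {len(incomplete)} species with incomplete traits excluded from "
            f"the modeling set (retained in the table)"
        )

    regional = pd.Index(
        sorted(_read_csv(regional_path, ["species_id"])["species_id"].unique())
    )
    known = set(regional) | set(tdf.index)

    occ_df = _read_csv(occurrences_path, _SCHEMAS["occurrences"])
    dup = occ_df.duplicated()
    if dup.any():
        report.duplicate_rows["occurrences"] = int(dup.sum())
        report.warn(f"occurrences: dropped {int(dup.sum())} duplicate (site, species) row(s)")
        occ_df = occ_df[~dup]
    unknown = sorted(set(occ_df["species_id"]) - known)
    if unknown:
        report.unknown_species["occurrences"] = unknown
        report.warn(f"occurrences: {len(unknown)} species not on the regional list")
    occ = OccurrenceTable(records=occ_df.reset_index(drop=True))

    community = None
    if community_path is not None:
        cdf = _read_csv(community_path, _SCHEMAS["community"])
        dup = cdf.duplicated(subset=["plot_id", "species_id"])
        if dup.any():
            report.duplicate_rows["community"] = int(dup.sum())
            report.warn(f"community: dropped {int(dup.sum())} duplicate (plot, species) row(s)")
            cdf = cdf[~dup]
        community = CommunityTable(records=cdf.reset_index(drop=True))

    colonists = None
    if colonists_path is not None:
        codf = _read_csv(colonists_path, _SCHEMAS["colonists"])
        missing_traits = sorted(set(codf["species_id"]) - set(traits.complete_species()))
        if missing_traits:
            report.unknown_species["colonists"] = missing_traits
            report.warn(
                f"colonists: {len(missing_traits)} species lack complete trait data and "
                f"will be skipped at prediction"
            )
        colonists = ColonistTable(records=codf.reset_index(drop=True))

    return traits, regional, occ, community, colonists, report
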