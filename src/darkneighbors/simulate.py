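"""Synthetic community assembly with known filtering truth.

Generates a regional trait cloud, a habitat pool carved out of it by a
Gaussian environmental filter, a community shaped by biotic filtering
(weak phenotype exclusion and/or limiting similarity per trait), plot
samples with skewed abundances, and a binomial seed-addition experiment
whose true establishment probabilities follow from the generative
filters.  Every draw is governed by a single seed, so all outputs are
bit-for-bit reproducible from (config, seed).

The generator emulates the qualitative structure of trait-based
assembly in species-rich grasslands: the habitat pool is clustered in
trait space, weak phenotype exclusion re-clusters the community around a
dominant phenotype, and limiting similarity disperses it by removing the
most similar pairs.  It does not emulate spatial structure, temporal
dynamics, dispersal limitation, or trait measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import (
    LEVEL_DARK,
    LEVEL_ENV_EXCLUDED,
    LEVEL_OBSERVED,
    ColonistTable,
    CommunityTable,
    OccurrenceTable,
    PoolAssignment,
    TableError,
    TraitTable,
)

WPE = "weak_phenotype_exclusion"
LS = "limiting_similarity"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic assembly.

    Defaults mirror a species-rich calcareous-grassland setting: a
    regional list of 600 species with two uniform traits, a Gaussian
    environmental filter of breadth 0.15 centred mid-range (admitting
    a pool of roughly 80–90 species), one trait under limiting
    similarity and one under weak phenotype exclusion, 40 plots of
    about 14 species each, and 15 seeds of each of 25 colonists added
    per plot.
    """

    n_regional: int = 600
    n_traits: int = 2
    env_optimum: tuple = (0.5, 0.5)
    env_sd: float = 0.15
    biotic_mode: tuple = (LS, WPE)
    wpe_optimum: float = 0.5
    wpe_sd: float = 0.12
    ls_min_distance: float = 0.015
    ls_kernel_sd: float | None = None   # defaults to ls_min_distance
    n_plots: int = 40
    plot_richness: int = 8              # mean of the per-plot Poisson richness
    count_geom_p: float = 0.3           # geometric parameter for counts (>=1)
    n_colonists: int = 25
    seeds_added: int = 15
    n_occurrence_sites: int = 7         # extra habitat sites for pool recovery
    occurrence_detection: float = 0.7   # per-site detection probability
    alien_fraction: float = 0.0
    min_pool: int = 20

    def __post_init__(self):
        if self.env_sd <= 0 or self.wpe_sd <= 0:
            raise ValueError("filter breadths must be positive")
        if not (0 < self.ls_min_distance < 1):
            raise ValueError("ls_min_distance must lie in (0, 1)")
        if len(self.env_optimum) != self.n_traits:
            raise ValueError("env_optimum length must equal n_traits")
        if len(self.biotic_mode) != self.n_traits:
            raise ValueError("biotic_mode length must equal n_traits")


@dataclass
class SimulatedAssembly:
    """A complete synthetic data set plus its generative truth."""

    config: SimulationConfig
    traits: TraitTable
    pool: PoolAssignment
    community: CommunityTable
    occurrences: OccurrenceTable
    colonists: ColonistTable
    colonist_traits: pd.DataFrame
    true_probability: pd.Series        # per-colonist P(env) * P(biotic)
    community_species: pd.Index


def _trait_names(n):
    return [f"trait_{i + 1}" for i in range(n)]


def _species_ids(n, prefix="sp"):
    width = len(str(n))
    return pd.Index([f"{prefix}{i + 1:0{width}d}" for i in range(n)], name="species_id")


def simulate_regional(config: SimulationConfig, rng: np.random.Generator) -> TraitTable:
    """Regional trait cloud: i.i.d. uniform trait values on [0, 1]."""
    if config.n_regional < 50:
        raise ValueError("regional list must hold at least 50 species")
    values = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(config.n_regional, config.n_traits)),
        index=_species_ids(config.n_regional),
        columns=_trait_names(config.n_traits),
    )
    kinds = {t: "continuous" for t in values.columns}
    return TraitTable(values=values, kinds=kinds, standardized=True)


def env_admission_probability(traits: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    """Gaussian acceptance kernel on distance to the environmental optimum."""
    opt = np.asarray(config.env_optimum, dtype=float)
    d2 = ((traits.to_numpy() - opt[None, :]) ** 2).sum(axis=1)
    return pd.Series(np.exp(-d2 / (2.0 * config.env_sd**2)), index=traits.index)


def apply_env_filter(
    traits: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.Index:
    """Bernoulli admission into the habitat pool under the Gaussian kernel."""
    p = env_admission_probability(traits, config)
    admitted = traits.index[rng.uniform(size=len(p)) < p.to_numpy()]
    if len(admitted) < config.min_pool:
        import warnings

        warnings.warn(
            f"habitat pool has only {len(admitted)} species (< {config.min_pool})"
        )
    return admitted


def wpe_retention_probability(x: np.ndarray, config: SimulationConfig) -> np.ndarray:
    return np.exp(-((x - config.wpe_optimum) ** 2) / (2.0 * config.wpe_sd**2))


def apply_weak_phenotype_exclusion(
    pool_traits: pd.DataFrame, trait, config: SimulationConfig, rng: np.random.Generator
) -> pd.Index:
    """Retain species with Gaussian probability around the dominant phenotype."""
    x = pool_traits[trait].to_numpy(dtype=float)
    p = wpe_retention_probability(x, config)
    kept = pool_traits.index[rng.uniform(size=len(p)) < p]
    if len(kept) == 0:
        raise TableError("weak phenotype exclusion removed every species")
    return kept


def apply_limiting_similarity(
    pool_traits: pd.DataFrame, trait, config: SimulationConfig, rng: np.random.Generator
) -> pd.Index:
    """Iteratively remove one member (at random) of the most similar pair on
    the affected trait until all pairwise distances reach the threshold."""
    species = list(pool_traits.index)
    x = dict(zip(species, pool_traits[trait].astype(float)))
    import warnings

    while len(species) >= 2:
        ordered = sorted(species, key=lambda s: (x[s], s))
        gaps = [
            (x[ordered[i + 1]] - x[ordered[i]], i) for i in range(len(ordered) - 1)
        ]
        gap, i = min(gaps)
        if gap >= config.ls_min_distance:
            break
        if len(species) == 2:
            warnings.warn(
                "limiting-similarity threshold unreachable; stopped at 2 species"
            )
            break
        drop = ordered[i + int(rng.integers(2))]
        species.remove(drop)
    return pd.Index(sorted(species), name="species_id")


def assemble_community(
    pool_traits: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.Index:
    """Apply each trait's biotic mode in turn to the habitat pool."""
    kept = pd.Index(pool_traits.index)
    for trait, mode in zip(pool_traits.columns, config.biotic_mode):
        sub = pool_traits.loc[kept]
        if mode == WPE:
            kept = apply_weak_phenotype_exclusion(sub, trait, config, rng)
        elif mode == LS:
            kept = apply_limiting_similarity(sub, trait, config, rng)
        elif mode == NEUTRAL:
            continue
        else:
            raise ValueError(f"unknown biotic mode {mode!r}")
    return pd.Index(sorted(kept), name="species_id")


def simulate_plots(
    community_species,
    config: SimulationConfig,
    rng: np.random.Generator,
    site_id: str = "site1",
) -> CommunityTable:
    """Plot samples: Poisson richness, species drawn without replacement,
    geometric (log-series-like) counts of at least one individual."""
    species = pd.Index(sorted(community_species))
    if len(species) == 0:
        raise TableError("empty community")
    rows = []
    import warnings

    for i in range(config.n_plots):
        richness = max(1, int(rng.poisson(config.plot_richness)))
        if richness > len(species):
            warnings.warn("plot richness truncated to community size")
            richness = len(species)
        chosen = rng.choice(len(species), size=richness, replace=False)
        counts = rng.geometric(config.count_geom_p, size=richness)
        for j, c in sorted(zip(chosen, counts)):
            rows.append((f"plot{i + 1:03d}", site_id, species[j], int(c)))
    return CommunityTable(
        records=pd.DataFrame(rows, columns=["plot_id", "site_id", "species_id", "count"])
    )


def simulate_occurrences(
    pool_species,
    observed_species,
    config: SimulationConfig,
    rng: np.random.Generator,
    focal_site: str = "focal",
) -> OccurrenceTable:
    """Occupancy lists for the focal site plus similar habitat sites.

    Each additional site detects each pool species independently with
    ``occurrence_detection`` probability, so the frequency rule of the
    pool constructor (≥ 2 sites) recovers the pool with high fidelity.
    """
    pool_species = pd.Index(sorted(pool_species))
    rows = [(focal_site, s) for s in sorted(observed_species)]
    for i in range(config.n_occurrence_sites):
        present = rng.uniform(size=len(pool_species)) < config.occurrence_detection
        rows += [(f"hab{i + 1}", s) for s in pool_species[present]]
    return OccurrenceTable(records=pd.DataFrame(rows, columns=["site_id", "species_id"]))


def true_biotic_probability(
    colonist_traits: pd.DataFrame,
    community_traits: pd.DataFrame,
    config: SimulationConfig,
) -> pd.Series:
    """Generative biotic passage probability per colonist.

    Product over traits of the mode's kernel: the weak-phenotype kernel
    for clustered traits, and for limiting similarity a saturating
    function of the nearest-neighbor gap (establishment is unlikely
    within the enforced spacing and likely beyond it)."""
    ls_sd = config.ls_kernel_sd or config.ls_min_distance
    p = np.ones(len(colonist_traits))
    for trait, mode in zip(colonist_traits.columns, config.biotic_mode):
        x = colonist_traits[trait].to_numpy(dtype=float)
        if mode == WPE:
            p = p * wpe_retention_probability(x, config)
        elif mode == LS:
            resident = community_traits[trait].to_numpy(dtype=float)
            d_nn = np.min(np.abs(x[:, None] - resident[None, :]), axis=1)
            p = p * (1.0 - np.exp(-(d_nn**2) / (2.0 * ls_sd**2)))
    return pd.Series(p, index=colonist_traits.index)


def simulate_seed_addition(
    colonist_traits: pd.DataFrame,
    community_traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    plot_ids,
    site_id: str = "site1",
):
    """Binomial seed-addition outcomes from the generative filters."""
    p_env = env_admission_probability(colonist_traits, config)
    p_bio = true_biotic_probability(colonist_traits, community_traits, config)
    true_p = (p_env * p_bio).rename("true_probability")
    rows = []
    n_alien = int(round(config.alien_fraction * len(colonist_traits)))
    aliens = set(colonist_traits.index[:n_alien])
    for sp in colonist_traits.index:
        outcomes = rng.binomial(config.seeds_added, true_p[sp], size=len(plot_ids))
        for plot, k in zip(plot_ids, outcomes):
            rows.append((sp, site_id, plot, config.seeds_added, int(k), sp not in aliens))
    colonists = ColonistTable(
        records=pd.DataFrame(
            rows,
            columns=["species_id", "site_id", "plot_id", "seeds_added",
                     "plants_year3", "is_native"],
        )
    )
    return colonists, true_p


def simulate_assembly(config: SimulationConfig, seed: int) -> SimulatedAssembly:
    """Run the full generative chain from one seed."""
    root = np.random.SeedSequence(seed)
    keys = root.spawn(6)
    rngs = [np.random.default_rng(k) for k in keys]

    traits = simulate_regional(config, rngs[0])
    pool_sp = apply_env_filter(traits.values, config, rngs[1])
    community_sp = assemble_community(traits.values.loc[pool_sp], config, rngs[2])
    community = simulate_plots(community_sp, config, rngs[3], site_id="site1")
    observed = pd.Index(sorted(community.records["species_id"].unique()))

    level = pd.Series(LEVEL_ENV_EXCLUDED, index=traits.species, name="level")
    level.loc[pool_sp.difference(observed)] = LEVEL_DARK
    level.loc[observed] = LEVEL_OBSERVED
    pool = PoolAssignment(
        table=pd.DataFrame(
            {"level": level, "in_regional": True,
             "in_habitat_pool": level != LEVEL_ENV_EXCLUDED}
        ),
        focal_site="focal",
    )

    occurrences = simulate_occurrences(pool_sp, observed, config, rngs[4])

    rng5 = rngs[5]
    col_ids = _species_ids(config.n_colonists, prefix="col")
    colonist_traits = pd.DataFrame(
        rng5.uniform(0.0, 1.0, size=(config.n_colonists, config.n_traits)),
        index=col_ids, columns=traits.traits,
    )
    colonists, true_p = simulate_seed_addition(
        colonist_traits, traits.values.loc[community_sp], config, rng5,
        plot_ids=list(community.plots), site_id="site1",
    )

    all_traits = TraitTable(
        values=pd.concat([traits.values, colonist_traits]),
        kinds=dict(traits.kinds),
        standardized=True,
        modeling_species=traits.species,
    )
    return SimulatedAssembly(
        config=config,
        traits=all_traits,
        pool=pool,
        community=community,
        occurrences=occurrences,
        colonists=colonists,
        colonist_traits=colonist_traits,
        true_probability=true_p,
        community_species=community_sp,
    )


def write_csvs(assembly: SimulatedAssembly, outdir) -> dict:
    """Emit the standard CSV schemas so downstream stages can run from files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tv = assembly.traits.values.copy()
    tv.index.name = "species_id"
    paths["traits"] = outdir / "traits.csv"
    tv.to_csv(paths["traits"])
    paths["regional"] = outdir / "regional.csv"
    pd.Series(assembly.pool.species, name="species_id").to_csv(
        paths["regional"], index=False
    )
    paths["occurrences"] = outdir / "occurrences.csv"
    assembly.occurrences.records.to_csv(paths["occurrences"], index=False)
    paths["community"] = outdir / "community.csv"
    assembly.community.records.to_csv(paths["community"], index=False)
    paths["colonists"] = outdir / "colonists.csv"
    assembly.colonists.records.to_csv(paths["colonists"], index=False)
    return paths
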