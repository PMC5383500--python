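"""Trait dissimilarities and functional-neighborhood distances.

On traits standardised to [0, 1] the single-trait Gower term is the
absolute difference and the multivariate Gower distance is the mean of
the per-trait terms.  A *functional neighborhood distance* of size k is
the mean distance from a focal species to its k most similar reference
species; k = 1 is the nearest-neighbor (NN) distance and k = n the mean
pairwise (MP) distance, so a grid of k interpolates between the two
classical metrics.

For biotic filtering, distances from a target species to the species
observed in a plot are abundance weighted (by within-plot relative
abundance) after centering the distance matrix, so that species more
similar than typical carry negative values and less similar ones
positive values of equal potential weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CommunityTable, PoolAssignment, TableError

MULTIVARIATE = "multivariate"
NN = "nn"

#: Neighborhood proportions used throughout: NN plus 10% increments.
SIZE_GRID = (NN, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A resolved neighborhood size.

    ``p`` is either ``"nn"`` or a proportion on the 10% grid; ``k`` the
    number of reference species included, computed as ⌈p·n⌉ (rounded up)
    for a reference set of size ``n``.
    """

    p: object  # "nn" or float in {0.1, ..., 1.0}
    k: int
    n: int

    def label(self) -> str:
        return "NN" if self.p == NN else f"{int(round(self.p * 100))}%"


def _tenths(p) -> int:
    """Map a grid proportion to integer tenths, validating membership."""
    tenths = round(float(p) * 10)
    if not (1 <= tenths <= 10) or abs(float(p) * 10 - tenths) > 1e-9:
        raise ValueError(f"neighborhood proportion {p!r} not on the NN/10% grid")
    return tenths


def resolve_neighborhood(p, n: int) -> NeighborhoodSpec:
    """Resolve a grid proportion (or ``"nn"``) to a member count for a
    reference set of size ``n``; proportions are always rounded up."""
    if n < 1:
        raise ValueError("reference-set size must be >= 1")
    if isinstance(p, str):
        if p.lower() != NN:
            raise ValueError(f"unknown neighborhood size {p!r}")
        return NeighborhoodSpec(NN, 1, n)
    tenths = _tenths(p)
    k = -(-tenths * n // 10)  # integer ceil of p*n, no float round-off
    return NeighborhoodSpec(tenths / 10, max(1, min(int(k), n)), n)


def resolve_k(p, n: int) -> int:
    """Member count for size ``p`` and reference-set size ``n`` (exact ceil)."""
    if isinstance(p, str):
        if p.lower() != NN:
            raise ValueError(f"unknown neighborhood size {p!r}")
        return 1
    return max(1, min(int(-(-_tenths(p) * n // 10)), n))


def pairwise_trait_distance(a: float, b: float) -> float:
    """Single-trait Gower term on [0, 1]-standardised values: |a - b|."""
    if np.isnan(a) or np.isnan(b):
        raise ValueError("missing trait value; caller must exclude incomplete species")
    return abs(a - b)


def gower_multivariate(row_a, row_b) -> float:
    """Multivariate Gower distance: mean per-trait absolute difference."""
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("trait rows must be nonempty and of equal length")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing trait values; no shared complete traits")
    return float(np.mean(np.abs(a - b)))


@dataclass
class DistanceTensor:
    """Per-trait (and optional multivariate Gower) pairwise dissimilarities."""

    focal: pd.Index
    reference: pd.Index
    per_trait: dict  # trait -> ndarray (len(focal), len(reference))
    multivariate: np.ndarray | None = None

    def matrix(self, trait) -> np.ndarray:
        if trait == MULTIVARIATE:
            if self.multivariate is None:
                raise KeyError("multivariate matrix not computed")
            return self.multivariate
        return self.per_trait[trait]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: (focal, reference, trait, distance)."""
        frames = []
        items = list(self.per_trait.items())
        if self.multivariate is not None:
            items.append((MULTIVARIATE, self.multivariate))
        for trait, mat in items:
            df = pd.DataFrame(mat, index=self.focal, columns=self.reference).stack()
            df = df.rename("distance").reset_index()
            df.columns = ["focal", "reference", "distance"]
            df.insert(2, "trait", trait)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def distance_tensor(
    traits: pd.DataFrame,
    focal,
    reference,
    with_multivariate: bool = True,
    extra_matrices: dict | None = None,
) -> DistanceTensor:
    """Per-trait |Δ| matrices between two species sets, plus the Gower mean.

    ``extra_matrices`` maps a name to a precomputed square distance
    DataFrame (e.g. cophenetic phylogenetic distances) treated as one
    additional "trait".
    """
    focal = pd.Index(focal)
    reference = pd.Index(reference)
    F = traits.loc[focal].to_numpy(dtype=float)
    R = traits.loc[reference].to_numpy(dtype=float)
    per_trait = {}
    for j, trait in enumerate(traits.columns):
        per_trait[trait] = np.abs(F[:, j][:, None] - R[:, j][None, :])
    multi = None
    if with_multivariate and per_trait:
        multi = np.mean(np.stack(list(per_trait.values())), axis=0)
    if extra_matrices:
        for name, mat in extra_matrices.items():
            per_trait[name] = mat.loc[focal, reference].to_numpy(dtype=float)
    return DistanceTensor(focal=focal, reference=reference, per_trait=per_trait,
                          multivariate=multi)


def read_square_matrix(path) -> pd.DataFrame:
    """Read a labelled square distance matrix CSV (species_id row/col labels)."""
    df = pd.read_csv(path, index_col=0)
    if not df.index.equals(pd.Index(df.columns)):
        raise TableError(f"{path}: row and column labels differ")
    return df.astype(float)


def neighborhood_distance(distances, k: int) -> float:
    """Mean of the k smallest distances (k = 1 → NN, k = all → MP)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty reference set")
    if not (1 <= k <= d.size):
        raise ValueError(f"k={k} outside [1, {d.size}]")
    return float(np.mean(np.sort(d)[:k]))


def _prefix_means(D: np.ndarray) -> np.ndarray:
    """Row-wise prefix means of sorted distances.

    ``out[i, k-1]`` is the mean of the k smallest finite entries of row i;
    positions beyond a row's finite count are NaN.  Entries to exclude
    (e.g. self-distances) should be set to +inf beforehand.
    """
    S = np.sort(D, axis=1)
    ks = np.arange(1, D.shape[1] + 1, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.cumsum(S, axis=1) / ks
    out[~np.isfinite(S)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Environmental-filter predictors

def env_predictor_tables(
    pool: PoolAssignment,
    traits: pd.DataFrame,
    sizes,
    basis: str = "per-trait",
    species=None,
):
    """Neighborhood distances from each species to the habitat pool.

    For every species in ``species`` (default: the regional list with
    trait data) and every size on ``sizes``, computes the per-trait (or
    multivariate) neighborhood distance to the habitat-pool members,
    excluding the species itself when it is a pool member.  Returns
    ``(designs, response)`` where ``designs[p]`` is a DataFrame of
    predictors and ``response`` the 0/1 pool-membership indicator.

    Each species is a data point: pool members are successes and
    environmentally excluded species failures.
    """
    pool_sp = pool.pool_species.intersection(traits.index[traits.notna().all(axis=1)])
    if len(pool_sp) == 0:
        raise TableError("habitat pool has no species with complete traits")
    pool_sp = pd.Index(sorted(pool_sp))
    if species is None:
        species = pool.species.intersection(traits.index[traits.notna().all(axis=1)])
    species = pd.Index(sorted(species))

    n = len(pool_sp)
    tensor = distance_tensor(traits, species, pool_sp,
                             with_multivariate=(basis == MULTIVARIATE))
    columns = [MULTIVARIATE] if basis == MULTIVARIATE else list(traits.columns)

    is_member = species.isin(pool_sp)
    member_pos = pool_sp.get_indexer(species)  # -1 for non-members
    valid = np.where(is_member, n - 1, n)
    if (valid == 0).any():
        raise TableError("a pool member has no neighbors (pool of size 1)")

    prefix = {}
    for col in columns:
        D = tensor.matrix(col).copy()
        rows = np.flatnonzero(is_member)
        D[rows, member_pos[rows]] = np.inf  # self-exclusion
        prefix[col] = _prefix_means(D)

    designs = {}
    for p in sizes:
        ks = np.minimum(resolve_k(p, n), valid)  # clamp for self-excluded members
        X = pd.DataFrame(
            {col: prefix[col][np.arange(len(species)), ks - 1] for col in columns},
            index=species,
        )
        designs[p] = X
    response = pd.Series(is_member.astype(int), index=species, name="in_pool")
    return designs, response


# ---------------------------------------------------------------------------
# Biotic-filter predictors

def compute_center(
    traits: pd.DataFrame,
    pool_species,
    site_species,
    basis: str = "per-trait",
) -> pd.Series:
    """Centering constants d̄ per trait: the grand mean of distances between
    habitat-pool species and all species observed anywhere at the site,
    excluding self-pairs."""
    pool_species = pd.Index(sorted(set(pool_species)))
    site_species = pd.Index(sorted(set(site_species)))
    if len(pool_species) == 0 or len(site_species) == 0:
        raise TableError("empty species set for distance centering")
    tensor = distance_tensor(traits, pool_species, site_species,
                             with_multivariate=(basis == MULTIVARIATE))
    shared = pool_species.intersection(site_species)
    n_pairs = len(pool_species) * len(site_species) - len(shared)
    if n_pairs == 0:
        raise TableError("no non-self pairs available for centering")
    columns = [MULTIVARIATE] if basis == MULTIVARIATE else list(traits.columns)
    center = {}
    ii = pool_species.get_indexer(shared)
    jj = site_species.get_indexer(shared)
    for col in columns:
        M = tensor.matrix(col)
        total = M.sum() - M[ii, jj].sum()  # self-distances are 0, kept for clarity
        center[col] = total / n_pairs
    return pd.Series(center, name="center")


def centered_weighted_distance(
    target,
    plot_counts: pd.Series,
    traits: pd.DataFrame,
    k: int,
    center: float,
    trait,
) -> float:
    """Reference implementation for a single (target, plot, trait) cell.

    Observed species j get weights w_j proportional to counts (excluding
    the target itself, then renormalised to sum to one) and signed values
    v_j = w_j (d_tj − d̄).  The k species with smallest v_j form the
    neighborhood; the value is Σ v_j over the neighborhood divided by the
    sum of their weights, so the k = all case reduces to Σ w_j (d − d̄).
    """
    counts = plot_counts.drop(index=target, errors="ignore").sort_index()
    total = counts.sum()
    if len(counts) == 0 or total <= 0:
        raise TableError("plot has no observed species with positive counts")
    w = (counts / total).to_numpy(dtype=float)
    if trait == MULTIVARIATE:
        d = np.array([
            gower_multivariate(traits.loc[target], traits.loc[j]) for j in counts.index
        ])
    else:
        x = traits.loc[counts.index, trait].to_numpy(dtype=float)
        d = np.abs(float(traits.loc[target, trait]) - x)
    v = w * (d - center)
    order = np.lexsort((np.arange(len(v)), v))  # ties broken by species_id order
    k = max(1, min(int(k), len(v)))
    sel = order[:k]
    return float(v[sel].sum() / w[sel].sum())


def biotic_design_tables(
    pool: PoolAssignment,
    community: CommunityTable,
    traits: pd.DataFrame,
    sizes,
    basis: str = "per-trait",
    center: pd.Series | None = None,
    targets=None,
):
    """Abundance-weighted centered neighborhood distances per (species, plot).

    Every habitat-pool species (or each species in ``targets``, e.g.
    colonists) is paired with every plot; predictors are the centered,
    abundance-weighted neighborhood values per trait, the response the
    species' presence in that plot.  The neighborhood of size p includes
    the ⌈p·m⌉ observed species with the smallest signed values, where m
    is the number of observed species available to the target in that
    plot (the target itself is never its own neighbor).

    Returns ``(frames, center)`` with ``frames[p]`` a tidy DataFrame with
    columns ``species_id, plot_id, present`` plus one column per trait.
    """
    complete = traits.index[traits.notna().all(axis=1)]
    pool_sp = pd.Index(sorted(pool.pool_species.intersection(complete)))
    if targets is None:
        targets = pool_sp
    targets = pd.Index(sorted(pd.Index(targets).intersection(complete)))
    if len(targets) == 0:
        raise TableError("no target species with complete traits")

    site_species = pd.Index(sorted(set(community.records["species_id"]) & set(complete)))
    if len(site_species) == 0:
        raise TableError("no observed species with trait data at the site")
    if center is None:
        center = compute_center(traits, pool_sp, site_species, basis=basis)

    columns = [MULTIVARIATE] if basis == MULTIVARIATE else list(traits.columns)
    tensor = distance_tensor(traits, targets, site_species,
                             with_multivariate=(basis == MULTIVARIATE))
    sizes = list(sizes)
    plots = community.plots
    n_t = len(targets)

    parts = {p: [] for p in sizes}
    for plot_id in plots:
        counts = community.plot_counts(plot_id)
        obs = pd.Index(sorted(set(counts.index) & set(site_species)))
        if len(obs) == 0:
            continue
        w_base = counts.loc[obs].to_numpy(dtype=float)
        w_base = w_base / w_base.sum()
        cols_idx = site_species.get_indexer(obs)

        self_pos = obs.get_indexer(targets)        # -1 if target not observed
        observed_here = self_pos >= 0
        m_valid = np.where(observed_here, len(obs) - 1, len(obs))
        if (m_valid == 0).any():
            # a target is the plot's only observed species: no neighbors
            keep = m_valid > 0
        else:
            keep = np.ones(n_t, dtype=bool)

        values = {}
        for col in columns:
            D = tensor.matrix(col)[:, cols_idx]
            v = w_base[None, :] * (D - float(center[col]))
            rows = np.flatnonzero(observed_here)
            v = v.copy()
            v[rows, self_pos[rows]] = np.inf  # self-exclusion; sorts last
            order = np.lexsort((np.broadcast_to(np.arange(len(obs)), v.shape), v))
            v_sorted = np.take_along_axis(v, order, axis=1)
            w_sorted = np.take_along_axis(
                np.broadcast_to(w_base, v.shape).copy(), order, axis=1
            )
            w_sorted[~np.isfinite(v_sorted)] = 0.0
            v_sorted[~np.isfinite(v_sorted)] = 0.0
            cv = np.cumsum(v_sorted, axis=1)
            cw = np.cumsum(w_sorted, axis=1)
            values[col] = (cv, cw)

        for p in sizes:
            ks = np.array([resolve_k(p, m) if m > 0 else 1 for m in m_valid])
            ks = np.minimum(ks, np.maximum(m_valid, 1))
            rows = np.arange(n_t)
            df = pd.DataFrame(
                {
                    col: values[col][0][rows, ks - 1] / values[col][1][rows, ks - 1]
                    for col in columns
                },
                index=targets,
            )
            df = df.loc[keep]
            df.insert(0, "present", observed_here[keep].astype(int))
            df.insert(0, "plot_id", plot_id)
            df.index.name = "species_id"
            parts[p].append(df.reset_index())

    frames = {}
    for p in sizes:
        if not parts[p]:
            raise TableError("no plots with observed species")
        frames[p] = pd.concat(parts[p], ignore_index=True)
    return frames, center
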