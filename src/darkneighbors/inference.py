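"""Neighborhood-size scans, model selection, establishment prediction and
validation against seed-addition outcomes.

For each filter a grid of candidate models (neighborhood size ×
interaction scheme) is fitted and ranked by AICc; candidates whose
diagnostics flag runaway estimates, insufficient distance variation or
separation are barred from selection even when their AICc is lowest.
The selected environmental and biotic models yield per-colonist passage
probabilities whose product is the predicted establishment probability,
validated by ordinary least squares against the observed proportion of
seeds establishing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distances import (
    NN,
    SIZE_GRID,
    NeighborhoodSpec,
    biotic_design_tables,
    env_predictor_tables,
    resolve_neighborhood,
)
from .models import (
    BIOTIC,
    ENVIRONMENTAL,
    FittedFilterModel,
    ModelSpec,
    backward_eliminate,
    diagnose,
    fit_biotic_model,
    fit_env_model,
    interaction_pairs,
    predict_biotic,
    predict_env,
)
from .tables import ORDINAL, TableError

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Ranked fits over the (size, scheme) grid for one filter."""

    filter: str
    table: pd.DataFrame                 # size, scheme, aicc, delta_aicc, ...
    models: dict                        # (size, scheme) -> FittedFilterModel
    selected: tuple                     # (size, scheme) key of the chosen model
    center: pd.Series | None = None     # biotic only: d̄ per trait

    @property
    def selected_model(self) -> FittedFilterModel:
        return self.models[self.selected]


def _rank_and_select(filter_name, models, raw_designs):
    rows = []
    for key, model in models.items():
        X_raw = raw_designs.get(key[0])
        flags = diagnose(model, X_raw)
        for flag in flags:
            if flag not in model.degenerate:
                model.degenerate.append(flag)
        rows.append(
            {
                "size": "NN" if key[0] == NN else key[0],
                "scheme": key[1],
                "aicc": model.aicc,
                "converged": model.converged,
                "degenerate": "; ".join(model.degenerate),
                "_key": key,
            }
        )
    table = pd.DataFrame(rows)
    finite = table.loc[np.isfinite(table["aicc"]), "aicc"]
    best_aicc = finite.min() if len(finite) else np.nan
    table["delta_aicc"] = table["aicc"] - best_aicc

    eligible = [
        (model.aicc, key)
        for key, model in models.items()
        if model.converged and not model.is_degenerate and np.isfinite(model.aicc)
    ]
    if not eligible:
        dump = table.to_string(index=False)
        raise TableError(
            f"all {filter_name} candidates are degenerate or unconverged:\n{dump}"
        )
    _, selected = min(eligible, key=lambda t: (t[0], str(t[1])))
    table = table.sort_values(["aicc", "scheme"], kind="stable").reset_index(drop=True)
    ordered = table.pop("_key")
    table["selected"] = [k == selected for k in ordered]
    return table[["size", "scheme", "aicc", "delta_aicc", "converged",
                  "degenerate", "selected"]], selected


def _scheme_models(fit_full, fit_none, refit_with, scheme, pairs):
    """Fit one scheme; parsimonious = backward elimination from all_pairwise."""
    if scheme == "none":
        return fit_none()
    full = fit_full()
    if scheme == "all_pairwise":
        return full
    if scheme == "parsimonious":
        if not full.converged:
            return full
        return backward_eliminate(refit_with, full)
    raise ValueError(f"unknown interaction scheme {scheme!r}")


def scan_env(
    pool,
    traits: pd.DataFrame,
    sizes=SIZE_GRID,
    schemes=("none",),
    basis: str = "per-trait",
    trait_kinds: dict | None = None,
    exclude_ordinal_interactions: bool = True,
) -> ScanResult:
    """Fit environmental-filter models over the size × scheme grid.

    Ordinal × ordinal interactions are excluded from the search space by
    default: ordinal neighborhood distances vary too little at small
    sizes for such products to be estimable.
    """
    designs, response = env_predictor_tables(pool, traits, sizes, basis=basis)
    predictor_names = tuple(next(iter(designs.values())).columns)
    exclude = []
    if exclude_ordinal_interactions and trait_kinds:
        ords = [t for t in predictor_names if trait_kinds.get(t) == ORDINAL]
        exclude = [(a, b) for i, a in enumerate(ords) for b in ords[i + 1:]]
    pairs = tuple(interaction_pairs(predictor_names, exclude))

    models = {}
    n_pool = int(response.sum())
    for p in sizes:
        X_raw = designs[p]
        nbhd = resolve_neighborhood(p, n_pool)

        def refit(interactions, _X=X_raw, _p=p, _nb=nbhd):
            spec = ModelSpec(ENVIRONMENTAL, _p, "parsimonious", predictor_names,
                             tuple(interactions), tuple(exclude))
            return fit_env_model(_X, response, spec, _nb)

        for scheme in schemes:
            spec = ModelSpec(ENVIRONMENTAL, p, scheme, predictor_names,
                             pairs if scheme != "none" else (), tuple(exclude))
            try:
                model = _scheme_models(
                    lambda s=spec: fit_env_model(X_raw, response, s, nbhd),
                    lambda s=spec: fit_env_model(X_raw, response, s, nbhd),
                    refit, scheme, pairs,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("env fit failed at size=%s scheme=%s: %s", p, scheme, exc)
                continue
            models[(p, scheme)] = model
    if not models:
        raise TableError("no environmental model could be fitted")
    table, selected = _rank_and_select(ENVIRONMENTAL, models, designs)
    return ScanResult(ENVIRONMENTAL, table, models, selected)


def scan_biotic(
    pool,
    community,
    traits: pd.DataFrame,
    sizes=SIZE_GRID,
    schemes=("none",),
    basis: str = "per-trait",
    n_quad: int = 15,
) -> ScanResult:
    """Fit biotic-filter mixed models over the size × scheme grid."""
    frames, center = biotic_design_tables(pool, community, traits, sizes, basis=basis)
    first = next(iter(frames.values()))
    predictor_names = tuple(
        c for c in first.columns if c not in ("plot_id", "species_id", "present")
    )
    pairs = tuple(interaction_pairs(predictor_names))

    models = {}
    raw_designs = {p: frames[p][list(predictor_names)] for p in sizes}
    for p in sizes:
        frame = frames[p]
        nbhd = resolve_neighborhood(p, frame["plot_id"].nunique())

        def refit(interactions, _f=frame, _p=p, _nb=nbhd):
            spec = ModelSpec(BIOTIC, _p, "parsimonious", predictor_names,
                             tuple(interactions))
            return fit_biotic_model(_f, spec, _nb, n_quad=n_quad)

        for scheme in schemes:
            spec = ModelSpec(BIOTIC, p, scheme, predictor_names,
                             pairs if scheme != "none" else ())
            try:
                model = _scheme_models(
                    lambda s=spec: fit_biotic_model(frame, s, nbhd, n_quad=n_quad),
                    lambda s=spec: fit_biotic_model(frame, s, nbhd, n_quad=n_quad),
                    refit, scheme, pairs,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("biotic fit failed at size=%s scheme=%s: %s", p, scheme, exc)
                continue
            models[(p, scheme)] = model
    if not models:
        raise TableError("no biotic model could be fitted")
    table, selected = _rank_and_select(BIOTIC, models, raw_designs)
    return ScanResult(BIOTIC, table, models, selected, center=center)


def combine(p_env, p_biotic):
    """Overall establishment probability: the product of filter passages."""
    return p_env * p_biotic


def predict_establishment(
    env_model: FittedFilterModel,
    biotic_model: FittedFilterModel,
    pool,
    traits: pd.DataFrame,
    community,
    colonist_species,
    center: pd.Series,
    basis: str = "per-trait",
    re_prediction: str = "plot",
    site_id=None,
) -> pd.DataFrame:
    """Per-colonist P(env), averaged P(biotic) and their product.

    Colonists are run through the fitted models with predictors computed
    at each model's own neighborhood size and standardization constants;
    the biotic probability is averaged over community samples (plots),
    with the colonist treated as absent from every plot.
    """
    complete = traits.index[traits.notna().all(axis=1)]
    colonists = pd.Index(sorted(set(colonist_species)))
    usable = colonists.intersection(complete)
    skipped = colonists.difference(usable)
    if len(skipped):
        logger.warning("colonists skipped for missing traits: %s", list(skipped))
    if len(usable) == 0:
        raise TableError("no colonist with complete trait data")

    env_designs, _ = env_predictor_tables(
        pool, traits, [env_model.spec.size], basis=basis, species=usable
    )
    p_env = predict_env(env_model, env_designs[env_model.spec.size])

    frames, _ = biotic_design_tables(
        pool, community, traits, [biotic_model.spec.size],
        basis=basis, center=center, targets=usable,
    )
    _, p_biotic = predict_biotic(
        biotic_model, frames[biotic_model.spec.size], re_prediction=re_prediction
    )

    out = pd.DataFrame({"p_env": p_env, "p_biotic": p_biotic.reindex(p_env.index)})
    out["p_overall"] = combine(out["p_env"], out["p_biotic"])
    out.index.name = "species_id"
    out = out.reset_index()
    out.insert(1, "site_id", site_id if site_id is not None else "site")
    return out


@dataclass
class ValidationResult:
    """OLS of actual on predicted establishment (plus site factor)."""

    slope: float
    slope_t: float
    slope_p: float
    adj_r2: float
    r2: float
    n: int
    site_terms: dict = field(default_factory=dict)
    subset: str = "all"
    note: str = ""


def validate(
    predicted: pd.Series,
    actual: pd.Series,
    sites: pd.Series | None = None,
    subset_species=None,
    subset_label: str = "all",
) -> ValidationResult:
    """Linear model of actual establishment on predicted establishment,
    with site as a factor when more than one site is present."""
    common = predicted.index.intersection(actual.index)
    if subset_species is not None:
        common = common.intersection(pd.Index(subset_species))
    common = pd.Index(sorted(common))
    yv = actual.loc[common].astype(float)
    xv = predicted.loc[common].astype(float)
    note = ""
    X = pd.DataFrame({"predicted": xv})
    site_terms = {}
    if sites is not None:
        site = sites.loc[common].astype(str)
        if site.nunique() > 1:
            dummies = pd.get_dummies(site, prefix="site", drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            note = "single site: site factor dropped"
    if len(common) < X.shape[1] + 3:
        raise TableError(f"too few species ({len(common)}) to validate")
    res = sm.OLS(yv.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    names = ["const"] + list(X.columns)
    params = pd.Series(res.params, index=names)
    tvals = pd.Series(res.tvalues, index=names)
    pvals = pd.Series(res.pvalues, index=names)
    for c in X.columns:
        if c.startswith("site_"):
            site_terms[c] = {"estimate": params[c], "t": tvals[c], "p": pvals[c]}
    return ValidationResult(
        slope=float(params["predicted"]),
        slope_t=float(tvals["predicted"]),
        slope_p=float(pvals["predicted"]),
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        n=len(common),
        site_terms=site_terms,
        subset=subset_label,
        note=note,
    )


def permutation_null_adj_r2(
    predicted: pd.Series,
    actual: pd.Series,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of adjusted R² from permuting predictions."""
    rng = rng or np.random.default_rng()
    common = pd.Index(sorted(predicted.index.intersection(actual.index)))
    y = actual.loc[common].to_numpy(dtype=float)
    x = predicted.loc[common].to_numpy(dtype=float)
    n = len(y)
    sst = np.sum((y - y.mean()) ** 2)
    out = np.empty(n_perm)
    ones = np.ones(n)
    for i in range(n_perm):
        xp = rng.permutation(x)
        A = np.column_stack([ones, xp])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        sse = np.sum((y - A @ coef) ** 2)
        r2 = 1.0 - sse / sst
        out[i] = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return out


def prediction_grid(
    env_scan: ScanResult,
    biotic_scan: ScanResult,
    pool,
    traits: pd.DataFrame,
    community,
    colonist_species,
    actual: pd.Series,
    sites: pd.Series | None = None,
    scheme: str | None = None,
    subset_species=None,
    subset_label: str = "all",
    basis: str = "per-trait",
    re_prediction: str = "plot",
    site_id=None,
) -> pd.DataFrame:
    """Adjusted R² of actual-vs-predicted establishment for every
    environmental × biotic neighborhood-size combination.

    Cells whose model is degenerate or unconverged are NaN (missing, not
    zero).  With single-size scans this reduces to a 1×1 grid equal to
    ``validate`` on those two models.
    """
    env_keys = {k[0]: k for k in env_scan.models if scheme is None or k[1] == scheme}
    bio_keys = {k[0]: k for k in biotic_scan.models if scheme is None or k[1] == scheme}
    env_sizes = list(env_keys)
    bio_sizes = list(bio_keys)

    grid = pd.DataFrame(
        np.nan,
        index=pd.Index(["NN" if s == NN else s for s in env_sizes], name="env_size"),
        columns=pd.Index(["NN" if s == NN else s for s in bio_sizes], name="biotic_size"),
    )
    for ei, es in zip(grid.index, env_sizes):
        em = env_scan.models[env_keys[es]]
        if not em.converged or em.is_degenerate:
            continue
        for bi, bs in zip(grid.columns, bio_sizes):
            bm = biotic_scan.models[bio_keys[bs]]
            if not bm.converged or bm.is_degenerate:
                continue
            pred = predict_establishment(
                em, bm, pool, traits, community, colonist_species,
                center=biotic_scan.center, basis=basis,
                re_prediction=re_prediction, site_id=site_id,
            ).set_index("species_id")
            try:
                res = validate(pred["p_overall"], actual, sites,
                               subset_species=subset_species,
                               subset_label=subset_label)
            except TableError:
                continue
            grid.loc[ei, bi] = res.adj_r2
    return grid
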