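"""Environmental- and biotic-filter models.

Environmental filtering: logistic regression over the regional list with
habitat-pool membership as the response and per-trait neighborhood
distances to the pool as predictors.  Biotic filtering: random-intercept
binomial mixed model over (habitat-pool species × plot) observations
with presence in the plot as the response, centered abundance-weighted
neighborhood distances as fixed effects and plot identity as the random
factor.

Predictors are z-scored before fitting, so coefficients are reported as
standardized estimates; interaction columns are products of z-scored
main effects, themselves z-scored.  Model comparison uses AICc, with
interaction terms optionally pruned by greedy backward elimination.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from . import glmm
from .distances import NN, NeighborhoodSpec

logger = logging.getLogger(__name__)

ENVIRONMENTAL = "environmental"
BIOTIC = "biotic"
SCHEMES = ("none", "all_pairwise", "parsimonious")

#: |standardized coefficient| above this, with p > .95, marks a runaway estimate.
RUNAWAY_COEF = 10.0
RUNAWAY_P = 0.95
#: raw predictors with sd / mean(|x|) below this have too little variation.
MIN_VARIATION_RATIO = 0.01


def interaction_pairs(traits, exclude_pairs=()):
    """All pairwise trait interactions, minus excluded pairs."""
    excluded = {frozenset(p) for p in exclude_pairs}
    return [
        (a, b)
        for a, b in itertools.combinations(traits, 2)
        if frozenset((a, b)) not in excluded
    ]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: filter × neighborhood size × interaction scheme."""

    filter: str                      # "environmental" | "biotic"
    size: object                     # "nn" or proportion on the 10% grid
    scheme: str = "none"
    traits: tuple = ()
    interactions: tuple = ()         # tuples of trait-name pairs actually included
    exclude_pairs: tuple = ()        # pairs barred from the search space

    def with_interactions(self, interactions):
        return replace(self, interactions=tuple(tuple(p) for p in interactions))


def standardize_predictors(X: pd.DataFrame, constants: pd.DataFrame | None = None):
    """z-score columns (sample sd); constant columns are zeroed and flagged.

    Returns ``(Z, constants, flags)`` where constants hold the mean/sd
    used, for identical application to prediction-time predictors.
    """
    if constants is None:
        mean = X.mean()
        sd = X.std(ddof=1)
        constants = pd.DataFrame({"mean": mean, "sd": sd})
    mean = constants["mean"].reindex(X.columns)
    sd = constants["sd"].reindex(X.columns)
    flags = [f"constant predictor: {c}" for c in X.columns[(sd == 0) | sd.isna()]]
    safe_sd = sd.replace(0.0, np.nan)
    Z = (X - mean) / safe_sd
    Z = Z.fillna(0.0)
    return Z, constants, flags


def build_design(X_raw: pd.DataFrame, spec: ModelSpec, constants: dict | None = None):
    """Assemble the standardized design matrix for a spec.

    Interaction columns (named ``a:b``) are formed from the z-scored main
    effects and then z-scored themselves.  ``constants`` from a fitted
    model reproduce the training-time standardization exactly.
    """
    mains = list(spec.traits) if spec.traits else list(X_raw.columns)
    X_raw = X_raw[mains]
    flags = []
    Zm, main_const, f = standardize_predictors(
        X_raw, None if constants is None else constants["mains"]
    )
    flags += f
    cols = {c: Zm[c] for c in mains}
    inter_raw = pd.DataFrame(
        {f"{a}:{b}": Zm[a] * Zm[b] for a, b in spec.interactions},
        index=X_raw.index,
    )
    if len(spec.interactions):
        Zi, inter_const, f = standardize_predictors(
            inter_raw, None if constants is None else constants["interactions"]
        )
        flags += f
        for c in Zi.columns:
            cols[c] = Zi[c]
    else:
        inter_const = pd.DataFrame(columns=["mean", "sd"])
    Z = pd.DataFrame(cols, index=X_raw.index)
    return Z, {"mains": main_const, "interactions": inter_const}, flags


def compute_aicc(loglik: float, k_params: int, n: int) -> float:
    """Small-sample Akaike criterion: −2ℓ + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k_params + 1:
        warnings.warn(f"AICc undefined for n={n} <= k+1={k_params + 1}; returning inf")
        return float("inf")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


@dataclass
class FittedFilterModel:
    """A fitted filter model with its selection and degeneracy metadata."""

    spec: ModelSpec
    neighborhood: NeighborhoodSpec | None
    params: pd.Series                  # includes "intercept"
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    k_params: int
    aicc: float
    converged: bool
    constants: dict
    degenerate: list = field(default_factory=list)
    re_sd: float | None = None         # biotic only
    plot_effects: pd.Series | None = None

    #: reasons that bar a model from selection; other flags (e.g. the
    #: zero-RE-variance fallback, which is still usable) are notes only
    DISQUALIFYING = ("runaway estimate", "insufficient distance variation", "separation")

    @property
    def is_degenerate(self) -> bool:
        return any(r.startswith(d) for r in self.degenerate for d in self.DISQUALIFYING)

    def linear_predictor(self, X_raw: pd.DataFrame) -> pd.Series:
        Z, _, _ = build_design(X_raw, self.spec, self.constants)
        coefs = self.params.drop("intercept")
        return self.params["intercept"] + Z[coefs.index] @ coefs

    def to_dict(self) -> dict:
        return {
            "filter": self.spec.filter,
            "size": self.spec.size,
            "scheme": self.spec.scheme,
            "traits": list(self.spec.traits),
            "interactions": [list(p) for p in self.spec.interactions],
            "coefficients": self.params.round(10).to_dict(),
            "bse": self.bse.round(10).to_dict(),
            "pvalues": self.pvalues.round(10).to_dict(),
            "loglik": self.llf,
            "n": self.n,
            "k_params": self.k_params,
            "aicc": self.aicc,
            "converged": self.converged,
            "degenerate": list(self.degenerate),
            "re_sd": self.re_sd,
            "constants": {
                block: df.to_dict(orient="index")
                for block, df in self.constants.items()
            },
        }


def _split_constant_columns(Z, flags):
    """Fit only non-constant columns; zeroed columns re-enter with coef 0."""
    const_cols = [f.split(": ", 1)[1] for f in flags if f.startswith("constant predictor")]
    fit_cols = [c for c in Z.columns if c not in const_cols]
    return fit_cols, const_cols


def _expand(series: pd.Series, all_names, fill) -> pd.Series:
    return series.reindex(["intercept"] + list(all_names), fill_value=fill)


def _finish_env_fit(res, Z, y, spec, neighborhood, constants, flags, converged):
    names = ["intercept"] + list(Z.columns)
    params = pd.Series(np.asarray(res.params), index=names)
    bse = pd.Series(np.asarray(res.bse), index=names)
    pvalues = pd.Series(np.asarray(res.pvalues), index=names)
    n = len(y)
    k = len(names)
    llf = float(res.llf)
    aicc = compute_aicc(llf, k, n) if converged else float("inf")
    return FittedFilterModel(
        spec=spec, neighborhood=neighborhood, params=params, bse=bse,
        pvalues=pvalues, llf=llf, n=n, k_params=k, aicc=aicc,
        converged=converged, constants=constants, degenerate=list(flags),
    )


def fit_env_model(
    X_raw: pd.DataFrame,
    y: pd.Series,
    spec: ModelSpec,
    neighborhood: NeighborhoodSpec | None = None,
) -> FittedFilterModel:
    """Maximum-likelihood logistic fit of pool membership on neighborhood
    distances (plus interactions per the spec's scheme)."""
    y = pd.Series(y).loc[X_raw.index].astype(int)
    if y.nunique() < 2:
        raise ValueError("environmental model needs both successes and failures")
    Z_full, constants, flags = build_design(X_raw, spec)
    fit_cols, const_cols = _split_constant_columns(Z_full, flags)
    Z = Z_full[fit_cols]
    if len(y) <= Z.shape[1] + 3:
        raise ValueError("too few species for the number of parameters")
    exog = np.column_stack([np.ones(len(Z)), Z.to_numpy()])
    model = sm.Logit(y.to_numpy(), exog)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        converged = bool(res.mle_retvals.get("converged", False))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.to_numpy(), exog).fit(
                disp=0, method="bfgs", maxiter=200, gtol=1e-6
            )
        converged = False
        flags = list(flags) + ["separation"]
    fitted = _finish_env_fit(res, Z, y, spec, neighborhood, constants, flags, converged)
    if const_cols:
        fitted.params = _expand(fitted.params, Z_full.columns, 0.0)
        fitted.bse = _expand(fitted.bse, Z_full.columns, np.nan)
        fitted.pvalues = _expand(fitted.pvalues, Z_full.columns, np.nan)
    if converged:
        prob = np.asarray(res.predict())
        if np.all((prob > 0.5) == (y.to_numpy() == 1)) and np.abs(
            fitted.params.drop("intercept")
        ).max() > 50:
            fitted.degenerate.append("separation")
            fitted.converged = False
            fitted.aicc = float("inf")
    return fitted


def fit_biotic_model(
    frame: pd.DataFrame,
    spec: ModelSpec,
    neighborhood: NeighborhoodSpec | None = None,
    n_quad: int = 15,
    min_re_sd: float = 0.05,
) -> FittedFilterModel:
    """Binomial mixed model: presence in the plot on centered, abundance-
    weighted neighborhood distances, with a plot random intercept.

    If the random-intercept variance collapses to (numerically) zero the
    model is refit as a plain logistic regression and flagged
    ``"zero RE variance"`` — still usable for prediction.
    """
    predictors = list(spec.traits) if spec.traits else [
        c for c in frame.columns if c not in ("plot_id", "species_id", "present")
    ]
    spec = replace(spec, traits=tuple(predictors))
    y = frame["present"].astype(int)
    if y.nunique() < 2:
        raise ValueError("biotic model needs both presences and absences")
    if frame["plot_id"].nunique() < 2:
        raise ValueError("biotic model needs at least two plots")
    X_raw = frame[predictors]
    Z_full, constants, flags = build_design(X_raw, spec)
    fit_cols, const_cols = _split_constant_columns(Z_full, flags)
    Z = Z_full[fit_cols]
    exog = np.column_stack([np.ones(len(Z)), Z.to_numpy()])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = sm.Logit(y.to_numpy(), exog).fit(disp=0, method="bfgs", maxiter=200)
    result = glmm.fit_binomial_mixed(
        exog, y.to_numpy(), frame["plot_id"].to_numpy(),
        n_quad=n_quad, start_beta=np.asarray(start.params), start_sd=0.5,
    )
    names = ["intercept"] + list(Z.columns)
    n = len(y)
    degenerate = list(flags)

    if result.re_sd <= min_re_sd:
        params = pd.Series(np.asarray(start.params), index=names)
        bse = pd.Series(np.asarray(start.bse), index=names)
        pvalues = pd.Series(np.asarray(start.pvalues), index=names)
        llf = float(start.llf)
        converged = bool(start.mle_retvals.get("converged", True))
        plots = pd.Index(sorted(frame["plot_id"].unique()), name="plot_id")
        effects = pd.Series(0.0, index=plots, name="intercept")
        re_sd = 0.0
        degenerate.append("zero RE variance")
    else:
        params = pd.Series(result.params, index=names)
        bse = pd.Series(result.bse, index=names)
        z = params / bse
        pvalues = pd.Series(2 * norm.sf(np.abs(z)), index=names)
        llf = result.loglik
        converged = result.converged
        effects = result.group_effects
        re_sd = result.re_sd

    k = len(names) + 1  # + random-intercept variance, counted uniformly
    if const_cols:
        params = _expand(params, Z_full.columns, 0.0)
        bse = _expand(bse, Z_full.columns, np.nan)
        pvalues = _expand(pvalues, Z_full.columns, np.nan)
    aicc = compute_aicc(llf, k, n) if converged else float("inf")
    return FittedFilterModel(
        spec=spec, neighborhood=neighborhood, params=params, bse=bse,
        pvalues=pvalues, llf=llf, n=n, k_params=k, aicc=aicc,
        converged=converged, constants=constants, degenerate=degenerate,
        re_sd=re_sd, plot_effects=effects,
    )


def backward_eliminate(refit, full: FittedFilterModel) -> FittedFilterModel:
    """Greedy backward elimination over interaction terms only.

    ``refit(interactions)`` must return a fitted model for the reduced
    term set; main effects are never dropped.  At each step the single
    interaction whose removal lowers AICc the most is dropped; stops when
    no removal improves AICc.
    """
    if not full.converged:
        raise ValueError("backward elimination requires a converged full model")
    best = full
    current = list(full.spec.interactions)
    improved = True
    while improved and current:
        improved = False
        candidates = []
        for drop in current:
            reduced = [p for p in current if p != drop]
            try:
                m = refit(reduced)
            except (ValueError, np.linalg.LinAlgError):
                continue
            candidates.append((m.aicc, drop, m))
        if candidates:
            aicc, drop, m = min(candidates, key=lambda c: c[0])
            if aicc < best.aicc:
                best = m
                current = [p for p in current if p != drop]
                improved = True
    return best


def exhaustive_eliminate(refit, full: FittedFilterModel, max_terms: int = 6) -> FittedFilterModel:
    """Best AICc over every subset of the interaction terms (≤ max_terms)."""
    pairs = list(full.spec.interactions)
    if len(pairs) > max_terms:
        raise ValueError(f"exhaustive search limited to {max_terms} interaction terms")
    best = full
    for r in range(len(pairs)):
        for subset in itertools.combinations(pairs, r):
            try:
                m = refit(list(subset))
            except (ValueError, np.linalg.LinAlgError):
                continue
            if m.aicc < best.aicc:
                best = m
    return best


def diagnose(model: FittedFilterModel, X_raw: pd.DataFrame | None = None) -> list:
    """Degeneracy screen: runaway standardized estimates, predictors with
    insufficient distance variation, and propagated separation flags."""
    flags = []
    coefs = model.params.drop("intercept")
    runaway = (coefs.abs() > RUNAWAY_COEF) & (model.pvalues.reindex(coefs.index) > RUNAWAY_P)
    for name in coefs.index[runaway]:
        flags.append(f"runaway estimate: {name}")
    if X_raw is not None:
        for col in X_raw.columns:
            x = X_raw[col].to_numpy(dtype=float)
            denom = np.mean(np.abs(x))
            if denom == 0 or np.std(x, ddof=1) / denom < MIN_VARIATION_RATIO:
                flags.append(f"insufficient distance variation: {col}")
    for reason in model.degenerate:
        if reason == "separation":
            flags.append("separation")
    return flags


def predict_env(model: FittedFilterModel, X_raw: pd.DataFrame) -> pd.Series:
    """Probability of passing the environmental filters per species."""
    eta = model.linear_predictor(X_raw)
    p = pd.Series(expit(eta), index=X_raw.index, name="p_env")
    return p.clip(1e-12, 1 - 1e-12)


def predict_biotic(
    model: FittedFilterModel,
    frame: pd.DataFrame,
    re_prediction: str = "plot",
):
    """Per-plot and plot-averaged probability of passing the biotic filters.

    ``frame`` holds one row per (species, plot) with the same predictor
    columns the model was fitted on (the colonist treated as absent from
    every plot).  With ``re_prediction="plot"`` each plot's estimated
    random intercept enters its prediction; ``"population"`` sets the
    random effect to zero.
    """
    X_raw = frame[list(model.spec.traits)]
    eta = model.linear_predictor(X_raw).to_numpy()
    if re_prediction == "plot" and model.plot_effects is not None:
        offsets = model.plot_effects.reindex(frame["plot_id"]).fillna(0.0).to_numpy()
    elif re_prediction == "population":
        offsets = 0.0
    else:
        raise ValueError(f"unknown re_prediction mode {re_prediction!r}")
    p = np.clip(expit(eta + offsets), 1e-12, 1 - 1e-12)
    per_plot = frame[["species_id", "plot_id"]].copy()
    per_plot["p_biotic"] = p
    averaged = per_plot.groupby("species_id")["p_biotic"].mean().sort_index()
    return per_plot, averaged


def coefficient_table(models: dict) -> pd.DataFrame:
    """Trait-by-model table of standardized estimates (NaN = term absent)."""
    cols = {}
    for label, model in models.items():
        cols[label] = model.params.drop("intercept")
    return pd.DataFrame(cols)
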