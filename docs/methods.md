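# Methods

This note documents the modelling choices in `darkneighbors`: the two
filter models, the neighborhood-distance machinery, the synthetic-data
generator, and the numerical decisions a maintainer would want recorded.

## Species pools

The framework operates on three nested species sets: the regional list,
the habitat-specific pool, and the observed community.  When built from
occupancy data (`build_habitat_pool`), a regional species enters the
pool if it occurs in at least `min_sites` sites of the habitat type
(default 2, which drops single-site records as likely misidentifications
or vagrants) **and** is on the regional list.  Species observed at the
focal site are always pool members, even if they fail the frequency
rule: they demonstrably occur there, and the framework's partition
requires observed ⊆ pool.  Occupancy records for species missing from
the regional list are ignored (such species may be unable to reach the
focal site).

## Trait preprocessing

Strongly right-skewed traits (height, SLA, seed weight in the grassland
setting) are natural-log transformed; the base is irrelevant after range
standardisation but fixed for reproducibility.  Every modelled trait is
then mapped to [0, 1] by min–max over the *modelling set* — the species
with complete traits on the regional list — and the same affine map is
applied to colonists, which may therefore fall outside [0, 1]; this is
logged, not an error.  Ordinal indicator values (Ellenberg F, N, L, R)
are rescaled by the same rule.  Species with any missing modelled trait
are excluded from model fitting but retained in tables and reports.  A
zero-range trait is a hard error naming the trait.

## Distances and neighborhoods

On standardised traits the single-trait Gower term is |Δ| and the
multivariate Gower distance the mean of per-trait terms.  The
neighborhood grid is NN plus 10% increments of the reference-set size,
member counts always rounded up (computed in integer arithmetic so
exact tenths never round up spuriously).  Ties in distance are broken by
species identifier, making neighborhood membership deterministic across
platforms.

A species is never its own neighbor: the focal species is excluded from
the reference set wherever it could appear (pool members in the
environmental design, observed species in their own plots).  Without
self-exclusion the zero self-distance would leak the response into the
predictor and degenerate the logistic fits.

Each trait's predictor uses the k nearest species under *that trait's*
distance (per-trait neighborhoods).  A shared multivariate neighborhood
is available via `basis="multivariate"`, and a precomputed square
distance matrix (e.g. cophenetic phylogenetic distances) can be supplied
as one additional "trait".

### Centering and abundance weighting (biotic filter)

Distances for the biotic model are centered, then abundance weighted:
v_j = w_j (d_tj − d̄), with w_j the within-plot relative abundance of
observed species j (self excluded, weights renormalised to one).  The
centering constant d̄ is computed per trait and per site as the grand
mean of distances between all habitat-pool species and all species
observed anywhere at the site, excluding self-pairs.  A per-site grand
mean keeps the constant stable across plots while giving "more/less
similar than typical" opposite signs.  Neighborhood inclusion ranks the
signed values ascending; the value reported for size k is the sum of the
k smallest v_j divided by the sum of their weights, so the k = all case
reduces exactly to Σ w_j (d − d̄) with Σw = 1 and values remain
comparable across k.  How to rank neighbors when abundances differ
wildly is genuinely open; the ascending-signed-value rule is a
documented choice, not inferred intent.

## Filter models

**Environmental.**  Logistic regression (statsmodels, Newton, tolerance
1e−8, 100 iterations) over the regional modelling set: pool membership
on per-trait neighborhood distances to the pool.  Predictors are
z-scored (sample sd, n−1); interaction columns are products of z-scored
mains, themselves z-scored; the constants are stored so prediction-time
predictors go through the identical map.  Perfect separation marks the
model unconverged with reason "separation" (coefficients from a BFGS
fall-back are reported for inspection).  Constant columns are retained
with coefficient zero and flagged.  Ordinal × ordinal interactions are
excluded from the environmental search space by default (ordinal
neighborhood distances vary too little at small sizes for such products
to be estimable); the exclusion is toggleable.

**Biotic.**  Random-intercept binomial mixed model over (pool species ×
plot) rows, fitted by marginal maximum likelihood with adaptive
Gauss–Hermite quadrature (15 nodes by default; nodes centred on each
plot's posterior mode and scaled by its curvature, reducing to the
Laplace approximation at one node).  No Python package in the
environment provides this estimator, so it is implemented in-package and
cross-checked in the test suite against `lme4::glmer` (nAGQ = 25):
coefficients and the random-intercept sd agree to ~1e−3, the marginal
log-likelihood to ~1e−3, and the log-likelihood is stable to 1e−6 under
restarts.  When the estimated random-intercept sd falls below 0.05 (a
negligible effect on the logit scale) the model is refit as a plain
logistic regression and flagged "zero RE variance"; it remains usable.
The variance parameter is counted in k for AICc in either case, keeping
candidate models comparable.

**AICc and selection.**  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), +∞ with a
warning when n ≤ k+1, and finite only for converged fits.  The
parsimonious interaction scheme is greedy backward elimination over
interaction terms only (main effects never drop): at each step remove
the single interaction whose removal lowers AICc most, stop at a local
minimum.  Greedy search matches the selection cost of large models; an
exhaustive check in the tests confirms the greedy optimum never exceeds
the full model and lies within the exhaustive range on small term sets.
The selected model is the minimum-AICc candidate that passes the
degeneracy screen: no runaway standardized estimates (|coef| > 10 with
p > .95), no predictor with sd/mean|x| < 0.01 before standardisation,
no separation.  AICc alone is deliberately not trusted: nearest-neighbor
distances can produce the lowest AICc together with absurd estimates, as
the low-variance fixtures in the tests demonstrate.

**Prediction.**  Colonist probabilities use each model's own
neighborhood size and standardization constants.  Biotic predictions
default to the plots' estimated random intercepts (plots are known
units, not new ones); population-level prediction (intercept 0) is
available via `re_prediction="population"`.  Per-plot probabilities are
averaged arithmetically; the overall establishment probability is the
product P(env) × P(biotic).  Per-coefficient p-values are reported
without multiple-testing correction; significance is marked at p < .05.

## Validation

Ordinary least squares of observed establishment (mean over plots of
plants in year three / seeds added) on predicted establishment, with
site as a factor when more than one site is pooled (dropped with a note
otherwise).  OLS on proportions is the default because establishment
proportions at these sample sizes are approximately continuous; the
reported adjusted R² uses the standard n, p penalty.  A permutation null
for the adjusted R² (`permutation_null_adj_r2`, predictions permuted
against outcomes, no site factor) provides a chance benchmark.  The
native-only subset is driven by an `is_native` column in the colonist
table.  The prediction grid repeats validation for every environmental ×
biotic size combination; cells whose model is degenerate or unconverged
are missing, not zero.

## Synthetic-data generator

The generator emulates trait-based assembly in a species-rich grassland
and is the package's test bed.  Defaults (one choice, stated here, used
throughout):

| parameter | default | meaning |
|---|---|---|
| `n_regional` | 600 | regional list size; traits i.i.d. uniform on [0, 1] |
| `n_traits` | 2 | trait dimensions |
| `env_optimum`, `env_sd` | (0.5, 0.5), 0.15 | Gaussian admission kernel exp(−‖t−opt‖²/2σ²); yields a pool of ~80–90 species |
| `biotic_mode` | (ls, wpe) | limiting similarity on trait 1, weak phenotype exclusion on trait 2 |
| `wpe_optimum`, `wpe_sd` | 0.5, 0.12 | retention kernel on the wpe trait, sharper than the pool spread so the community clusters |
| `ls_min_distance` | 0.015 | iterative most-similar-pair removal until all gaps reach this |
| `n_plots`, `plot_richness` | 40, 8 | Poisson plot richness; plots sample roughly half the community |
| `count_geom_p` | 0.3 | geometric counts ≥ 1 (log-series-like skew) |
| `n_colonists`, `seeds_added` | 25, 15 | binomial seed addition per plot |

Gaussian acceptance kernels are the simplest mechanism that is monotone
in distance and produces trait clustering; most-similar-pair removal is
the most direct mechanism for dispersion.  A colonist's true
establishment probability is the product of the environmental kernel and
per-trait biotic kernels — the wpe retention kernel for clustered
traits, and for dispersed traits 1 − exp(−d_nn²/2σ²) of the
nearest-neighbor gap to the community (establishment unlikely within the
enforced spacing, likely beyond it).  Established plants are binomial
draws per plot from that probability.

The generator also emits an occupancy table (the focal site plus
`n_occurrence_sites` habitat sites, each detecting pool species with
probability 0.7) so the pool constructor can be exercised end to end;
the frequency rule recovers >90% of the true pool under the defaults.

What the generator does **not** emulate: spatial structure within and
between plots, temporal dynamics, dispersal limitation, trait
measurement error, covariance between traits, and detection error in the
occupancy lists.  Passing tests therefore demonstrate that the
estimators recover the generative filters under idealised sampling, not
that any particular field system satisfies those assumptions.

## Reproducibility and problem sizes

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, so every output is bit-for-bit
reproducible from (config, seed); the workflow archives the config
verbatim and two identical runs produce byte-identical CSVs.  The
statistical test batteries use 100 replicates per claim (sign recovery,
selection behaviour, end-to-end validation against a 1,000-permutation
null) at the default generator sizes; the distance and AICc oracles run
at 100–10,000 random instances with 1e−12 agreement.  The packaged demo
runs use 250–600 regional species and 8–40 plots — large enough for the
phenomena, small enough to keep a full suite run in a few minutes.

## Known limitations

- The biotic mixed model supports a single random intercept (plot);
  nested or crossed random effects are out of scope.
- Gower handling of categorical traits and missing-data pair weighting
  is not implemented; species with incomplete traits are excluded from
  fitting instead.
- Backward elimination is greedy; with many interacting traits the
  selected term set may be a local AICc minimum.
- The validation regression treats establishment proportions as
  continuous; a binomial GLM alternative would weight species by seeds
  sown and is not the default.
- The workflow runs one site at a time; multi-site validation is
  supported at the `validate()` level by pooling per-site predictions.
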