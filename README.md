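# darkneighbors

Predicting species establishment from **dark diversity** and
**functional-neighborhood** trait distances.

## The problem

Whether a species can establish in a community depends on two filters:
an *environmental* filter (does it have the traits the habitat
requires?) and a *biotic* filter (can it cope with the resident
community?).  Both filters leave signatures in trait space, but they are
confounded when only the observed community is analysed.  Splitting the
regional species list into three groups separates them:

- **environmentally excluded** — regional species outside the
  habitat-specific species pool;
- **dark diversity** — pool members absent from the focal community
  (they could live there but biotic interactions keep them out);
- **observed** — species present in the community.

Contrasting pool members with environmentally excluded species isolates
the environmental filter; contrasting observed species with the dark
diversity isolates the biotic filter.  `darkneighbors` implements this
comparison for plant communities (or any system with a species × trait
table), fits both filters as regressions on trait dissimilarity, and
turns them into establishment predictions for new colonists.

## The model

Traits are range-standardised to [0, 1] (log first where flagged), so
the per-trait Gower dissimilarity is |Δ| and the multivariate Gower
distance the mean of per-trait terms.  The **functional neighborhood
distance** of size *k* from species *i* to a reference set is the mean
distance to its *k* most similar members:

    FND_k(i) = (1/k) Σ_{j ∈ k nearest} d_ij

*k* = 1 is the nearest-neighbor (NN) distance, *k* = n the mean pairwise
(MP) distance; a grid of sizes (NN, 10%, 20%, …, 100% of the reference
set, counts rounded up) interpolates between the two classical metrics.

- **Environmental filter** — logistic regression over the regional list:
  `Pr(i ∈ pool) = logit⁻¹(β₀ + Σ_t β_t FND_k(i, pool; trait t))`,
  one predictor per trait (optionally their pairwise interactions),
  predictors z-scored so coefficients are standardized estimates.
- **Biotic filter** — random-intercept binomial mixed model over
  (pool species × plot) observations: presence in the plot regressed on
  *centered, abundance-weighted* neighborhood distances to the plot's
  observed species (weights = within-plot relative abundance, distance
  matrix centered first so "more similar than typical" carries a
  negative sign), with plot identity as the random factor.  Negative
  trait coefficients indicate clustering (weak phenotype exclusion),
  positive ones dispersion (limiting similarity).
- **Selection** — candidate models over the size × interaction-scheme
  grid are ranked by AICc; candidates with runaway estimates
  (|coef| > 10 with p > .95), insufficient distance variation or
  separation are barred from selection regardless of AICc.
- **Prediction** — a colonist's overall establishment probability is
  P(env) × P(biotic), the biotic part averaged over plots; predictions
  are validated by OLS of the observed proportion of established seeds
  on the prediction (site as a factor when several sites are pooled).

A synthetic-assembly generator with known truth (Gaussian environmental
kernel, weak-phenotype-exclusion kernel, iterative most-similar-pair
removal for limiting similarity, plot sampling, binomial seed addition)
makes every stage testable without field data.

## Worked example

```python
import darkneighbors as dn

assembly = dn.simulate_assembly(dn.SimulationConfig(), seed=1)
env = dn.scan_env(assembly.pool, assembly.traits.values,
                  sizes=["nn", 0.3, 1.0], schemes=("none",))
print(env.table[["size", "scheme", "aicc", "delta_aicc"]].to_string(index=False))
```

prints

```
size scheme       aicc  delta_aicc
 1.0   none 321.896378    0.000000
 0.3   none 328.305589    6.409211
  NN   none 393.242952   71.346574
```

— on this single-cluster habitat pool the mean-pairwise distance
describes environmental filtering best and the nearest neighbor worst
(ΔAICc ≈ 71).  The selected model's standardized coefficients,

```
intercept   -3.395
trait_1     -2.002
trait_2     -1.671
```

are both negative: species functionally close to the habitat pool are
more likely to pass the environmental filter.  Running the full pipeline
(`examples/04_full_pipeline.py`) adds the biotic scan, per-colonist
predictions and validation; with the default generator the 25 colonists'
predicted establishment is significantly related to realised
establishment (slope t = 2.11, p = 0.046, adjusted R² = 0.13 for seed 1).

The `examples/` directory holds one short script per capability:
simulation, neighborhood distances, filter fitting, and the end-to-end
pipeline.  A thin CLI wraps the same machinery:

```bash
darkneighbors run --config config.yaml --seed 1 --outdir myrun
darkneighbors report myrun
```

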