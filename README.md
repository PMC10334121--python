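# ffagg

Hierarchical Bayesian modelling of surface forage-fish aggregations (FFAs)
from aerial strip surveys: how many aggregations a grid cell holds, how
large they are, and how much prey surface area that makes available to
surface-foraging predators.

Aerial digital surveys photograph a few percent of a shelf sea per flight
and record each visible surface school with its traced area (m²).  The
resulting counts per 4 × 4 km cell are zero-heavy, overdispersed, seasonal
and spatially autocorrelated.  `ffagg` provides:

- **Abundance**: a zero-inflated negative binomial model, built as the
  Poisson–Gamma–Bernoulli mixture
  `y ~ Poisson(λρz)`, `ρ ~ Gamma(r, r)`, `z ~ Bernoulli(ψ)`, with
  `logit ψ = α₁ + β_sea·x_sea` (season only; summer reference),
  `log λ = μ + u_k + Σ β_l x_l + log(effort km²)`, and `u` a proper
  Gaussian CAR field over 32 km blocks,
  `u ~ MVN(0, (I − γC)⁻¹M/τ)` — fitted by a seeded adaptive
  Metropolis-within-Gibbs sampler with the latents marginalised.
- **Size**: `log s ~ N(μₛ + u2_k + Σ βˢ_l x_l, σ²)` with a second CAR field.
- **Diagnostics**: split-R̂, effective sample size, Freeman–Tukey posterior
  predictive checks `T = Σ(√y − √e)²` with Bayesian p-values, and k-fold
  cross-validation (Pearson for abundance, Spearman for size).
- **Prediction**: seasonal gridded abundance, size, and surface
  availability (abundance × size, draw-wise), plus covariate response
  curves with credible bands.
- **Community layer**: species richness, k-means community types with
  deterministic elbow selection, prevalence per type, and FFA density per
  type, from externally supplied occurrence-probability grids.
- **Synthetic seascape**: a generator producing grids, smooth correlated
  covariates, strip-survey effort, ZINB counts, lognormal sizes and planted
  occurrence grids, so the whole pipeline runs and is tested with no data
  download.

The estimators follow scikit-learn conventions (`fit`, `predict`,
`get_params`; fitted attributes end in `_`) and compose with sklearn
cloning and model selection.

## Worked example

```python
from ffagg import (SimulationConfig, simulate_dataset, ZINBAbundanceModel,
                   posterior_predictive_check)

world = simulate_dataset(SimulationConfig(seed=7))   # 2,500 cells, 8 surveys
model = ZINBAbundanceModel(random_state=11, standardize=False)
model.fit(world["counts"], adjacency=world["grid"].coarse_adjacency)
print(model.coef_summary_.head())
```

On the default synthetic world this recovers the generative truth
(intercept −1, β ∈ [−1, 1], r = 1.5): all ten 95% credible intervals cover
their true coefficients, e.g.

```
   parameter    median   ci95_lo   ci95_hi  significant
   beta[bpi]    -1.003    -1.079    -0.926         True   # truth -1.0
   beta[chla]    0.507     0.449     0.565         True   # truth  0.5
   r             1.573     ...                            # truth  1.5
```

with split-R̂ < 1.03 and ESS > 400 for every covariate effect
(3 chains × 20,000 iterations, ≈4.5 min on one CPU).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the stated desk scale:
simulates the synthetic seascape, fits both hierarchical models at the
desk MCMC protocol, runs the Freeman–Tukey posterior predictive checks, a
fivefold cross-validation, seasonal prediction maps with surface
availability, and the community layer, printing a summary as it goes
(≈6 min on one CPU).  A run with `--seed 1` printed:

```
[sim] 11050 surveyed (cell, survey) rows, 15170 aggregations, 81% zero rows
[abundance] fitted in 281s; max beta PSRF 1.025, min ESS 340
[abundance] Freeman-Tukey Bayesian p-value: 0.753
[size] Bayesian p-value: 0.980
[cv] out-of-sample r = 0.465 ± 0.064 (in-sample 0.469)
[predict:summer] median abundance/cell 6.901, median size 68.1 m^2, median availability 323.8 m^2
[predict:winter] median abundance/cell 0.464, median size 68.1 m^2, median availability 21.8 m^2
[community] K* = 4; mean richness by type: 7.4, 5.4, 5.0, 4.3; FFA density range 0.2118-0.4773 per km^2
```

The seasonal contrast (summer ≫ winter), the non-extreme abundance p-value
and the close in-/out-of-sample correlations are the expected behaviour of
a well-specified model on its own synthetic world.  The project defines no
numeric acceptance targets, so the JSON object the script writes is empty.

## Command line

A thin CLI wraps the library for scripted pipelines:

```bash
ffagg simulate --seed 1 --out sim/
ffagg grid --extent 0,0,200,200 --fine 4 --factor 8 --out grid/
ffagg rasterize --ffa points.csv --footprints fp.csv --grid grid/ --out tables/
ffagg fit-abundance --counts sim/counts.csv --grid sim/ --out fit/
ffagg fit-size --sizes sim/sizes.csv --grid sim/ --out fit/
ffagg cluster --occurrence sim/occurrence.csv --k 2,8 --out comm/
```

All tables are plain CSV; fit configuration is YAML mapped onto the
estimator constructor arguments.

See `docs/methods.md` for the model details, sampler design, numerical
choices and known limitations.
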