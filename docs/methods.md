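# Methods

## The problem

Aerial digital strip surveys photograph narrow transects of sea surface and
record every visible forage-fish aggregation (FFA) — a cohesive surface
school detected as one object — together with its traced surface area.
Coverage is partial (a few percent of the study area per survey) and counts
are extremely zero-heavy and overdispersed, with strong seasonality and
spatial structure.  `ffagg` models two per-aggregation quantities on a
nested planar grid: how many aggregations a cell holds (abundance) and how
large they are (size), and combines them into surface availability, a proxy
for prey accessible to surface-foraging predators.  A post-processing layer
summarises externally supplied species occurrence grids into richness and
k-means community types and overlays FFA density on them.

## Abundance model

Counts y_ij (fine cell i, survey j) follow a zero-inflated
Poisson–Gamma mixture, i.e. a zero-inflated negative binomial:

    y_ij ~ Poisson(lambda_ij * rho_ij * z_ij)
    rho_ij ~ Gamma(r, r)            # mean-1 heterogeneity, NB dispersion r
    z_ij ~ Bernoulli(psi_ij)        # presence
    logit psi_ij = alpha1 + beta_sea . x_sea(ij)      # season only
    log lambda_ij = log theta_ij + e_ij               # e_ij = log surveyed km^2
    log theta_ij = mu + u_k(i) + sum_l beta_l x_ijl   # 10 covariates

with u a proper Gaussian conditional autoregressive (CAR) field over the
coarse blocks: u ~ MVN(0, (I − γC)^{-1} M / τ_CAR), C the row-normalised
binary rook contiguity matrix, M = diag(1/m_k).  The likelihood is
evaluated with ρ and z marginalised (exact; better mixing); sampling the
latents explicitly is available as `marginalize=False` and targets the same
posterior.  Season affects only the presence probability ψ (reference
level: summer); covariates and space act on the conditional intensity θ.
The effort offset is the natural log of surveyed area in km², so expected
counts scale exactly with sampling effort.

Assumptions worth noting: ψ carries no covariates or spatial term; a single
CAR field is shared by all surveys (space is static); covariates enter
linearly on the log scale after standardisation.

## Size model

Logged surface areas are Gaussian:

    log s_a ~ N(mu_a, sigma^2),  mu_a = mu_s + u2_k(a) + sum_l betaSize_l x_al

with an independent second CAR field u2 and the same covariate suite at the
aggregation's cell and date.  No season term and no effort offset (sizes
are properties of detected aggregations, not of sampling).  σ is a single
homoscedastic residual SD.  Back-transformed sizes are reported as the
lognormal median exp(μ) by default (`back_transform="mean"` gives
exp(μ + σ²/2)).

## Priors and sampler

Priors are minimally informative and configurable: Normal(0, 10²) on all
regression-type coefficients (β, β_sea, α1, intercepts), half-Normal(10)
on r, Gamma(1, 0.01) on the CAR and residual precisions, Uniform over
[0, γ_max − ε) on the spatial dependence γ (the full propriety interval is
available with `gamma_support="full"`).

Both models run Metropolis-within-Gibbs:

- covariate block: adaptive random-walk Metropolis with an empirical
  proposal covariance and step size tuned toward 23.4% acceptance
  (diminishing adaptation, gain ∝ t^-0.6);
- the CAR field: single-site updates swept colour-by-colour over a greedy
  colouring of the block graph (two colours on a rook lattice), so blocks
  that share no edge move simultaneously;
- τ_CAR, and in the size model everything except γ: conjugate Gibbs;
- γ: scalar Metropolis using the precomputed contiguity spectrum for the
  O(n) log-determinant;
- a likelihood-invariant *recentering* Gibbs move that shifts the intercept
  by δ and the whole CAR field by −δ, with δ drawn from its exact Gaussian
  conditional.  The intercept and the field mean are near-unidentified;
  without this move the intercept's split-Rhat exceeds 5 at desk scale.
  The intercept deliberately has its own scalar kernel: folding it into the
  covariate block lets the recentering jumps corrupt the adapted proposal
  covariance and collapses the mixing of the other coefficients.

The default desk protocol is 3 chains × 20,000 iterations, 50% burn-in,
thin 4 (7,500 retained draws); the full field protocol (3 × 400,000,
250,000 burn-in, thin 20) is reachable through the same knobs.  With the
default synthetic world this passes split-Rhat < 1.1 and ESS > 400 on all
covariate effects in ≈4–5 minutes on one CPU.

The data-augmentation mode mixes well in small, weakly structured problems
and is verified against the marginal sampler there; at full spatial scale
the (ψ, r) ridge requires flipping many z's jointly and the augmented
chains move too slowly to be useful.  That is why marginalisation is the
default and not merely a preference.

## Diagnostics

- split-Rhat (each chain halved before the between/within variance ratio)
  and Geyer initial-positive-sequence ESS, cross-checked against arviz in
  the test suite.  Conventions: zero-variance draws give Rhat 1.0 and ESS
  equal to the total draw count, with warnings.
- Posterior predictive checks use the Freeman–Tukey discrepancy
  T = Σ (√y − √e)², with e the per-row expected value at each retained
  draw and replicates simulated from the full observation model; the
  Bayesian p-value is Pr(T_rep ≥ T_obs) with ties favouring the replicate.
  For the size model the check runs on the back-transformed m² scale,
  which keeps every input non-negative.
- k-fold cross-validation permutes rows under a seed, deals them into k
  near-equal folds, and scores abundance with Pearson and size with
  Spearman correlation (average ranks; sizes have extreme outliers).
  Held-out rows in coarse blocks never seen in training take the CAR field
  at its marginal mean — no conditional kriging across the graph; the
  simplest defensible rule, and it is logged per fold.

## Prediction

Seasonal maps push a per-cell covariate grid through the posterior draws.
Abundance maps are expected counts at a reference surveyed area of one
full cell (16 km²; configurable) so "per cell" has a concrete meaning.
Surface availability is the draw-wise product of abundance and size draws
— never a product of summaries — paired by index after truncating to the
shorter draw sequence, since the two models are fitted independently.
Cells whose standardised covariates fall outside ±4 training SDs are
flagged as extrapolations.  Response curves sweep one covariate across its
observed range with the others at their training means and the field at
its marginal mean.

## Community layer

Occurrence-probability grids (from an external joint species distribution
model; fitting one is out of scope) are reduced to stacked richness
(per-cell sum of probabilities), k-means community types, per-type species
prevalence, and FFA abundance/density per type.  K is chosen by a
deterministic elbow rule: the ratio of successive total-WSS drops,
maximised over interior candidate K (ties to the smaller K).  The raw
second difference of WSS was tried first and systematically under-picked K
— with geometrically decaying drops the absolute curvature peaks one K too
early — so the ratio form, which normalises by local scale, replaced it.
Types are labelled 1..K in decreasing mean richness, so type 1 is always
the richest community.  Covariate screening iteratively removes the
covariate with the largest VIF until all VIF < 3, then resolves remaining
pairs with |r| > 0.6 by dropping the member with the larger mean absolute
correlation; the procedure is deterministic and idempotent.  Sample SDs
(n−1) are used throughout.

## Synthetic seascape

The generator states a world rather than tuning one: a 200 × 200 km extent
of 4-km cells in 10 × 10-cell blocks (2,500 cells, 25 blocks); ten
standardised Gaussian-smoothed covariate fields (16 km correlation length,
three static, selected pairs cross-correlated at 0.4–0.5); eight surveys
(two per season) of parallel 584-m strips at 7% coverage with random
phase; counts and sizes simulated from the full generative model with
intercept −1, β spanning [−1, 1], r = 1.5, γ = 0.8, τ_CAR = 2, mean size
exp(4.57) ≈ 96.5 m², σ_size = 0.8, and seasonal presence 0.7 / 0.5 / 0.2 /
0.05 (summer / autumn / spring / winter).  These magnitudes echo the
seasonal ordering and right-skewed sizes of real surface-aggregation
surveys while remaining recoverable on one CPU in minutes.  Dynamic
covariates blend a persistent field with per-survey redraws in equal
variance shares.  What the generator does *not* emulate: real ocean
dynamics (fronts, eddies, advection), detection error, survey-platform
differences, or temporal drift in the spatial field — so a green recovery
test establishes correctness of the inference machinery under the model's
own assumptions, not realism of the model for any particular shelf
ecosystem.

## Numerical choices

- ZINB zero mass assembled with log1p/logaddexp; gammaln(y + r) cached and
  reused across proposals that do not change r.
- CAR log-determinants via the eigenvalues of D^{-1/2} W D^{-1/2}, computed
  once per graph; γ's propriety interval is (1/λ_min, 1) and the sampler
  keeps γ at least 10⁻³ inside it.  Isolated blocks fall back to
  independent N(μ, 1/τ) with a warning; an edgeless graph samples γ over
  (0, 1) where it is inert.
- Degenerate inputs: zero-effort rows must be removed before fitting
  (offsets need positive area); constant covariate columns are rejected at
  standardisation and dropped with a warning at screening; a zero-variance
  CV fold scores NaN with a warning rather than failing the run.

## Known limitations

- The presence component ψ is season-only by design; real zero inflation
  may covary with environment and space.
- Cross-validation re-fits with the same protocol per fold; for the full
  field protocol this is expensive, and the CV entry point is normally run
  at reduced settings (documented wherever used).
- The PPC's calibration under fixed true parameters is uniform by
  construction — extreme p-values occur 10% of the time even for a
  perfectly specified model; PPC p-values from fitted posteriors are
  conservative (concentrated near 0.5) as usual.
- Availability pairs abundance and size draws by index; any real
  cross-model dependence between abundance and size is not represented.
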