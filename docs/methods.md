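# Methods

## Model

The data are counts `Y_ij` of animal species `j` recorded on plant
individual `i`, where each individual belongs to a plant species `k = k[i]`
and every individual was watched for the same standardised time. Keeping the
individual level is deliberate: replicate individuals of the same plant
species act as repeated detection trials, which is what lets the model
separate an animal's abundance from whether the species pair interacts at
all.

The hierarchy has three layers:

* **Observation.** `Y_ij ~ Poisson(θ_kj · λ_j)`. When the pair does not
  interact (`θ_kj = 0`) the Poisson mean is zero, so the only possible count
  is zero — a structural zero, distinct from a sampling zero where
  `θ_kj = 1` but nothing happened to be seen.
* **Abundance.** `log λ_j = β0 + β1_j`, with `β1_j ~ N(0, σ_β²)`. λ is an
  expected count per standardised observation, shared across plant species.
  A per-pair abundance `λ_kj` would be identifiable in principle but
  multiplies the parameter count by the number of plant species and is not
  modelled.
* **Interaction and availability.** `θ_kj ~ Bernoulli(Θ_kj)` with
  `Θ_kj = ω_j · logit⁻¹(ψ_kj)`, `ψ_kj = α0 + α1_kj`, `α1_kj ~ N(0, σ_α²)`,
  and `ω_j ~ Bernoulli(Ω)`. The binary `ω_j` says whether species `j` is
  present in the community at all; an absent species has interaction
  probability exactly zero. Note the zero-inflated composition is the only
  self-consistent reading of the availability construction: putting `ω`
  inside the logit would give absent species an interaction probability of
  one half.

**Richness by data augmentation.** The observed `n` animal species are
padded with `m` all-zero pseudo-species (labels `aug_0000`, ...) to a
supercommunity of fixed size `S = n + m`, and total richness is the derived
quantity `N = Σ_j ω_j`. `S` caps the estimable richness, so the richness
interval is checked against the ceiling and flagged when it touches it.
Augmented species are exchangeable; only aggregate quantities are reported
for them, never per-pseudo-species estimates (label switching makes those
meaningless). A single shared `Ω` is used — the availability probability is
a community-level quantity, not species-specific (with all-zero data for
every augmented column there is nothing to separate species-level `Ω_j`).

**Priors.** `σ_α, σ_β ~ half-Cauchy(0, 10)` truncated to the positive
half-line; `Ω ~ U(0, 1)`; `α0, β0 ~ N(0, 10²)` (weakly informative, on the
logit and log scales respectively).

## Sampling

Inference is Metropolis-within-Gibbs, fully vectorised over the
(plant species × animal species) grid:

* `θ`, `Ω` have exact full conditionals. A pair with any positive count has
  `θ_kj = 1` with certainty; otherwise `θ` is Bernoulli with the
  zero-truncation-corrected probability `qE/(qE + 1 − q)`, where
  `E = exp(−n_k λ_j)` is the probability of seeing nothing across the
  `n_k` individuals of plant `k`.
* `ω_j` is updated with `θ` collapsed out column-wise (the marginal
  likelihood of an all-zero column is `Π_k (q_kj E_kj + 1 − q_kj)`), then
  `θ` is redrawn given `ω` — a blocked Gibbs move that avoids the sticky
  joint mode at `ω = θ = 0`. Species with any observed count have `ω = 1`
  forced by the data.
* Continuous blocks (`α0`, `α1`, `σ_α`, `β0`, `β1`, `σ_β`) use random-walk
  Metropolis with per-block scales adapted during burn-in toward acceptance
  rates of roughly 0.35–0.4 and frozen afterwards. Random effects with no
  likelihood exposure (columns with `ω_j = 0`, species with no active `θ`)
  are drawn directly from their priors.
* Two extra exact moves handle the intercept/random-effect ridge, along
  which only the sum is likelihood-identified: a translation move
  (`intercept + δ`, `effects − δ`) for both regressions, and a coordinated
  log-scale rescale of `(σ_α, α1)` that follows the half-Cauchy tail. Both
  are plain MH moves on the exact posterior; without them the heavy-tailed
  `σ_α` direction mixes an order of magnitude slower.

Chains are initialised independently from dispersed starting points; four
chains are the default. Convergence is judged by the potential scale
reduction factor `sqrt(((n−1)/n·W + B/n)/W)` per scalar parameter with a
1.1 threshold, plus arviz effective sample sizes. `continue_fit` extends
non-converged chains from their stored final states, mirroring the
update-and-recheck protocol; the scenario study does this once per cell and
flags cells that still fail. A `prior_only` mode disables every likelihood
factor; the chain then targets the joint prior, which the tests use to
verify the sampler recovers prior moments of `Ω`, `σ_α`, `σ_β`.

Default chain layout for simulation-scale fits: burn-in 10% of iterations,
thinning 100. The full-data protocol in the literature is internally
inconsistent about burn-in (100,000 vs 10,000 for a 10⁶-iteration run), so
both are left configurable rather than hard-coded.

Numerical guards: inverse-logit probabilities clipped to
`[1e−12, 1 − 1e−12]`; `exp` arguments capped at 700; the log-likelihood
uses the log-space Poisson pmf with the convention `Poisson(y|0) = [y = 0]`,
returning −inf (not an exception) for impossible configurations.

## Simulator

The generator mirrors the model's own data-generating assumptions: one
`θ` per species pair (individuals are exchangeable replicates), one `λ` per
animal species, and Poisson observation. Scenario hyperparameters follow
the factorial design: interaction scores `ψ_kj ~ N(μ_ψ, 2.5²)` on the logit
scale with `μ_ψ ∈ {1.5, −2.5}` (high ≈ 80% of pairs interacting, low ≈ 8%),
and `log λ_j ~ N(μ_λ, 1.5²)` with `μ_λ ∈ {0, −3}` (high ≈ one animal per
observation at the median, low ≈ one per twenty). Communities are 10 plant
× 150 animal species with 20, 40 or 60 sampled individuals per plant
species; the four presets HIHA/HILA/LIHA/LILA cross the two factors. Three
RNG streams (hyperparameters, truth realisation, sampling) are spawned per
seed so that changing the sampling effort holds the true network fixed.

"True" species-level weighted networks use expected weights `θ_kj·λ_j`
scaled by 60 individuals per plant — the largest effort in the design — as
the reference; WNODF and H2′ are insensitive to uniform rescaling, so the
choice of constant matters little. Sampled and predicted networks use
counts.

What the simulator does *not* emulate: spatial or temporal covariates,
phenology, traits and forbidden links, per-individual attractiveness
differences within a plant species, and observer effects. Passing the
recovery tests therefore shows the estimator is correct under its own
assumptions at realistic sizes and detection regimes — not that those
assumptions hold for any particular field dataset.

## Network metrics

* **Degree distributions** are complementary cumulative (P(degree ≥ d)) per
  guild, over nonzero links.
* **WNODF** orders rows and columns by decreasing marginal totals; an
  ordered pair contributes only when its totals strictly decrease (ties
  contribute zero), the pairwise term being the percentage of the lower
  line's nonzero cells that are strictly smaller than the corresponding
  cells of the upper line. The statistic is the mean over all row and
  column pairs. Note a widespread implementation variant (e.g. vegan's
  `nestednodf`) conditions pairs on decreasing binary *fill* instead of
  totals; on these simulated networks the two variants differ by a factor
  of about two, and the totals-based definition is the one whose levels
  match the reference values reproduced here.
* **H2′** standardises the Shannon entropy of the interaction distribution
  between its extremes under fixed marginal totals:
  `(H2max − H2)/(H2max − H2min)`, clipped to [0, 1]. `H2min` uses the
  greedy largest-remaining-margin packing heuristic (tolerance 1e−6; exact
  integer optimisation is out of scope). `H2max` is the entropy of the
  independence allocation, integer-constrained for count matrices (floor of
  expected cells plus greedy distribution of the remainder), continuous
  otherwise.
* **Modularity** maximises Barber's weighted bipartite
  `Q = (1/F) Σ_ij (A_ij − k_i d_j / F) δ(g_i, h_j)` by alternating
  best-label sweeps (label propagation) with greedy module merging, from 20
  restarts by default (one deterministic all-singleton start plus random
  partitions); ties break to the lowest label, and a species may open a
  fresh module when every existing one has negative affinity. Exhaustive
  partition search verifies global optimality on instances up to 6 × 6.
* Empty rows/columns are dropped before any metric (unobserved species
  carry no structure); the count dropped is logged. Ensembles report the
  mean and a conservative central 95% interval (lower/higher quantile
  methods, so two networks give exactly min/max); a metric failure on one
  ensemble member is excluded and counted rather than aborting.

## Evaluation

Binary interaction recovery is scored by ROC/AUC of the posterior mean
`θ_kj` against the simulated truth, restricted to species present in the
truth (augmented columns have no defined truth value). Abundance recovery
reports per-species 95% interval coverage and log-scale RMSE of posterior
medians; species that truly interact with no plant are excluded from the
aggregate scores — their data are all structural zeros, so their abundance
estimates collapse to the prior mode by construction. Partner-count
comparisons set true, sampled and estimated values side by side; sampled
counts can only miss links, never invent them.

The scenario study runs the full preset × effort grid at a "desk" profile
(5 plants × 30 animals, supercommunity +20, 4 × 20,000 iterations) chosen
so a single CPU covers a cell in about a minute; the "full" profile
(10 × 150, +250, 4 × 200,000) reproduces the complete design and is
correspondingly slow. The reduced recovery and augmentation-robustness
experiments in the test suite use the desk profile sizes (robustness:
supercommunities of +50/+100/+200 on a low-abundance dataset, 4 × 10,000
iterations each).

## Known limitations

* The `σ_α` posterior is intrinsically heavy-tailed whenever the pair
  indicators are nearly saturated (high-interaction regimes): the
  likelihood only bounds it from below. The ridge moves make this mixable,
  but point summaries of `σ_α` should be read as scale indicators, not
  precise estimates.
* H2′ levels of sparse low-interaction networks are sensitive to the
  entropy-bound conventions; the values produced here are internally
  consistent (0 at independence, 1 at perfect specialisation, verified to
  1e−6) but published figures computed with other H2min/H2max conventions
  can differ materially. The specialisation level reported for
  low-interaction simulated networks (≈0.55–0.6) is reproducible under
  every convention implemented here.
* Partner counts for plants (`NA_k`) sum over the supercommunity, so they
  include undetected species and routinely exceed the observed counts by
  design; the output metadata records this choice.
* No covariates on `ψ` (phylogeny, traits, environment) and no
  host-switching/re-wiring dynamics; the estimated interaction breadth is a
  static snapshot.
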