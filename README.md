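# coextnet

Bipartite interaction networks — who pollinates whom, who visits which
flower — are almost always undersampled: rare insects go undetected, and
real interactions are missed simply because nobody was watching at the right
moment. Metrics computed on the observed network (nestedness, specialisation,
modularity, partner counts) are then biased, and so is any coextinction-risk
assessment built on them.

`coextnet` estimates the *true* interaction structure from imperfectly
detected count data. It implements a hierarchical zero-inflated Poisson
N-mixture model for plant-individual × animal-species interaction counts,
with Bayesian data augmentation for the species that were never detected at
all, plus a factorial scenario simulator and the weighted network metrics
needed to compare true, sampled and model-predicted networks. It is aimed at
community ecologists working with flower-visitation (or comparable bipartite
count) data.

## The model

The count of animal species *j* on plant individual *i* of plant species
*k* is modelled as

```
Y_ij      ~ Poisson(θ_kj · λ_j)              observation layer
log λ_j   = β0 + β1_j                        abundance regression
θ_kj      ~ Bernoulli(Θ_kj)                  pair interaction indicator
Θ_kj      = ω_j · logit⁻¹(α0 + α1_kj)        zero-inflation / availability
ω_j       ~ Bernoulli(Ω)                     species present at all?
```

with priors β1_j ~ N(0, σ_β²), α1_kj ~ N(0, σ_α²), σ ~ half-Cauchy(0, 10),
Ω ~ U(0, 1), and N(0, 10²) on the intercepts. The observed community of *n*
animal species is augmented with *m* all-zero pseudo-species to a
"supercommunity" of fixed size S = n + m, so that total richness is
estimated as N = Σ_j ω_j and partner counts as NP_j = Σ_k θ_kj (plants per
animal) and NA_k = Σ_j θ_kj (animals per plant) — the coextinction-risk
proxies. Inference is Metropolis-within-Gibbs (exact conditionals for θ, ω,
Ω; adaptive random-walk blocks for the rest), with the plain potential-
scale-reduction factor (Rhat) as the convergence diagnostic.

## Worked example

Simulate a reduced "high interaction, low abundance" community (the regime
typical of real flower-visitation data), refit it, and summarise:

```python
from coextnet import (preset_config, simulate_scenario, augment_dataset,
                      ZIPNMixtureModel)

cfg = preset_config("HILA", samples_per_plant=20, seed=42,
                    n_plants=5, n_animals=30)
truth, _, observed, kept = simulate_scenario(cfg)
print(f"observed {observed.n_observed} of {truth.n_animals} animal species")

ds = augment_dataset(observed, 50)                   # supercommunity of 75
results = ZIPNMixtureModel(ds).fit(n_chains=4, n_iter=10_000, thin=50, seed=1)
print(results.summary().round(3))
print(results.species_richness())
low, high = results.detection_completeness()
print(f"detection completeness {low:.0f}-{high:.0f}%")
```

prints

```
observed 25 of 30 animal species
               mean      sd    q2.5  median    q97.5   rhat
parameter
alpha0        5.831   4.335   0.674   4.828   16.317  1.052
beta0        -4.494   0.951  -6.444  -4.477   -2.883  1.010
sigma_alpha  22.173  50.052   0.926  10.427  131.662  1.009
sigma_beta    2.154   0.576   1.196   2.131    3.401  1.009
Omega         0.640   0.176   0.345   0.621    0.980  1.005
N            48.293  12.814  29.000  47.000   74.000  1.005
richness N = 48 (29, 74); observed 25 of supercommunity 75
detection completeness 34-86%
```

Five of the thirty simulated species were never detected; the posterior for
total richness N covers the truth (30) and the completeness interval says
the survey may have seen as little as a third of the community. Per-species
partner counts with credible intervals come from `results.partner_counts()`,
and `results.posterior_predictive_networks(1000)` draws a network ensemble
for metric uncertainty (`coextnet.ensemble_metrics`).

A thin CLI mirrors the stages: `coextnet simulate | fit | summarize |
metrics | study` (see `--help` on each).

## Network metrics

`coextnet.metrics` provides the four structural metrics used throughout:
per-guild degree distributions, weighted nestedness WNODF (pairs ordered by
decreasing marginal totals; 0–100), specialisation H2′ (Shannon entropy
standardised between its marginal-constrained extremes, with an
integer-constrained upper bound for count matrices; 0–1), and weighted
bipartite modularity maximised by label propagation with agglomerative
refinement over Barber's Q.

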