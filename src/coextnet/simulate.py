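"""Factorial scenario simulator for bipartite interaction networks.

Ground truth is generated in two layers that mirror the fitted model: a
binary plant-species × animal-species interaction matrix θ drawn from
Bernoulli(inv-logit ψ), with pair scores ψ_kj ~ Normal(μ_ψ, σ_ψ²) on the
logit scale, and per-animal expected abundances λ_j with log λ_j ~
Normal(μ_λ, σ_λ²).  Observation is Poisson sampling of each animal on each
plant individual: Y_ij ~ Poisson(θ_{k[i]j}·λ_j).

The four named presets cross high/low mean interaction probability with
high/low mean abundance (HIHA, HILA, LIHA, LILA); combined with 20/40/60
sampled individuals per plant species they span the twelve study scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .data import InteractionDataset, augment_dataset

__all__ = [
    "ScenarioConfig",
    "TrueNetwork",
    "PRESETS",
    "preset_config",
    "draw_hyperparameters",
    "simulate_true_network",
    "sample_network",
    "strip_unobserved",
    "simulate_scenario",
]

#: reference number of individuals per plant used to scale expected weights
#: of "true" networks (the largest sampling effort in the study design)
REFERENCE_EFFORT = 60

#: (interaction logit mean, log-abundance mean) for the four factorial presets
PRESETS: dict[str, tuple[float, float]] = {
    "HIHA": (1.5, 0.0),
    "HILA": (1.5, -3.0),
    "LIHA": (-2.5, 0.0),
    "LILA": (-2.5, -3.0),
}

INTERACTION_SD = 2.5
ABUNDANCE_SD = 1.5


@dataclass(frozen=True)
class ScenarioConfig:
    """Hyperparameters and dimensions of one simulation scenario."""

    interaction_mu: float
    interaction_sd: float = INTERACTION_SD
    abundance_mu: float = 0.0
    abundance_sd: float = ABUNDANCE_SD
    n_plants: int = 10
    n_animals: int = 150
    samples_per_plant: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction_sd < 0 or self.abundance_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if min(self.n_plants, self.n_animals, self.samples_per_plant) < 1:
            raise ValueError("dimensions must be positive")


def preset_config(name: str, *, samples_per_plant: int = 20, seed: int = 0,
                  n_plants: int = 10, n_animals: int = 150) -> ScenarioConfig:
    """Scenario configuration for a named preset (HIHA/HILA/LIHA/LILA)."""
    try:
        mu_psi, mu_lam = PRESETS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return ScenarioConfig(
        interaction_mu=mu_psi,
        abundance_mu=mu_lam,
        samples_per_plant=samples_per_plant,
        seed=seed,
        n_plants=n_plants,
        n_animals=n_animals,
    )


@dataclass
class TrueNetwork:
    """Simulated ground truth for one scenario.

    ``theta`` is the binary interaction matrix, ``psi`` the logit-scale pair
    scores it was drawn from, ``lam`` the expected per-observation abundance
    of each animal, and ``expected_weights`` the species-level weighted
    network θ_kj·λ_j scaled by ``effort`` individuals per plant.
    """

    theta: np.ndarray
    psi: np.ndarray
    lam: np.ndarray
    expected_weights: np.ndarray
    effort: int = REFERENCE_EFFORT

    @property
    def n_plants(self) -> int:
        return self.theta.shape[0]

    @property
    def n_animals(self) -> int:
        return self.theta.shape[1]

    def partner_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """True (plant partners per animal, animal partners per plant)."""
        return self.theta.sum(axis=0), self.theta.sum(axis=1)


def draw_hyperparameters(cfg: ScenarioConfig, rng: np.random.Generator):
    """Draw pair scores ψ (logit scale) and abundances λ for one scenario."""
    psi = rng.normal(cfg.interaction_mu, cfg.interaction_sd, size=(cfg.n_plants, cfg.n_animals))
    lam = np.exp(rng.normal(cfg.abundance_mu, cfg.abundance_sd, size=cfg.n_animals))
    return psi, lam


def simulate_true_network(cfg: ScenarioConfig, psi: np.ndarray, lam: np.ndarray,
                          rng: np.random.Generator,
                          effort: int = REFERENCE_EFFORT) -> TrueNetwork:
    """Realize the binary interaction matrix and the expected weighted network.

    Animals (or plants) whose θ row/column is all zero are kept: they exist
    in truth even if they interact with nothing.
    """
    psi = np.asarray(psi, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if psi.shape != (cfg.n_plants, cfg.n_animals) or lam.shape != (cfg.n_animals,):
        raise ValueError("psi/lam shape does not match the scenario dimensions")
    theta = (rng.random(psi.shape) < expit(psi)).astype(np.int8)
    expected = theta * lam * effort
    return TrueNetwork(theta=theta, psi=psi, lam=lam, expected_weights=expected, effort=effort)


def sample_network(truth: TrueNetwork, cfg: ScenarioConfig,
                   rng: np.random.Generator) -> InteractionDataset:
    """Observe the true network: Poisson counts on replicate plant individuals.

    Each plant species contributes ``cfg.samples_per_plant`` individuals;
    counts are Y_ij ~ Poisson(θ_{k[i]j}·λ_j).  Animal columns that drew all
    zeros are retained (use :func:`strip_unobserved` to drop them as a field
    study implicitly would).
    """
    if cfg.samples_per_plant < 1:
        raise ValueError("samples_per_plant must be >= 1")
    K, S = truth.theta.shape
    plant_of = np.repeat(np.arange(K), cfg.samples_per_plant)
    mu = truth.theta[plant_of] * truth.lam  # (I, S)
    counts = rng.poisson(mu).astype(np.int64)
    width = len(str(S))
    return InteractionDataset(
        counts=counts,
        plant_species_of=plant_of,
        plant_labels=[f"plant_{k:02d}" for k in range(K)],
        animal_labels=[f"animal_{j:0{width}d}" for j in range(S)],
        individual_labels=[f"plant_{k:02d}_ind_{r:03d}"
                           for k in range(K) for r in range(cfg.samples_per_plant)],
        n_observed=S,
        metadata={"samples_per_plant": cfg.samples_per_plant},
    )


def strip_unobserved(ds: InteractionDataset) -> tuple[InteractionDataset, np.ndarray]:
    """Drop animal columns with no detections, as field data implicitly do.

    Returns the observed-only dataset and the array of retained column
    indices in the original (truth) ordering, for later evaluation.
    """
    kept = np.nonzero(ds.counts.any(axis=0))[0]
    out = ds.copy()
    out.counts = ds.counts[:, kept]
    out.animal_labels = [ds.animal_labels[j] for j in kept]
    out.n_observed = kept.size
    out.m_augmented = 0
    out.validate()
    return out, kept


def simulate_scenario(cfg: ScenarioConfig, *, m_augment: int = 0):
    """Run one full scenario: truth, sampled observations, observed dataset.

    Three independent RNG streams (hyperparameters / truth realization /
    sampling) are spawned from ``cfg.seed``, so varying the sampling effort
    leaves the underlying true network fixed.

    Returns ``(truth, full_dataset, observed_dataset, kept_indices)`` where
    ``observed_dataset`` has unobserved columns stripped and, if requested,
    ``m_augment`` all-zero pseudo-species appended.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_hyper, rng_truth, rng_sample = (np.random.default_rng(s) for s in ss.spawn(3))
    psi, lam = draw_hyperparameters(cfg, rng_hyper)
    truth = simulate_true_network(cfg, psi, lam, rng_truth)
    full = sample_network(truth, cfg, rng_sample)
    observed, kept = strip_unobserved(full)
    if m_augment:
        observed = augment_dataset(observed, m_augment)
    return truth, full, observed, kept


def with_effort(cfg: ScenarioConfig, samples_per_plant: int) -> ScenarioConfig:
    """Same scenario at a different sampling effort (truth streams unchanged)."""
    return replace(cfg, samples_per_plant=samples_per_plant)
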