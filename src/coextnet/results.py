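"""Posterior results: diagnostics, summaries and derived quantities.

:class:`ZIPNMixtureResults` wraps the thinned MCMC draws and exposes the
headline outputs of the analysis:

* per-species partner counts NP_j (plant partners of animal j) and NA_k
  (animal partners of plant k) — the coextinction-risk proxies,
* total species richness N = sum_j omega_j over the supercommunity,
* detection completeness (observed richness over the richness interval),
* posterior-predictive network ensembles for metric uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SpeciesMatrix
from .model import MCMCConfig, ZIPNMixtureModel, rhat

__all__ = [
    "ZIPNMixtureResults",
    "PosteriorSamples",
    "PartnerCountSummary",
    "RichnessSummary",
    "partner_counts",
    "species_richness",
    "detection_completeness",
    "posterior_predictive_networks",
]

_QUANTS = {"q2.5": 0.025, "q25": 0.25, "median": 0.5, "q75": 0.75, "q97.5": 0.975}


def _ess(draws: np.ndarray) -> float:
    """Effective sample size (bulk) of (chain, draw) samples via arviz."""
    import arviz as az

    out = az.ess(np.asarray(draws, dtype=float))
    if hasattr(out, "to_array"):
        return float(np.asarray(out.to_array()).squeeze())
    return float(out)


@dataclass
class PartnerCountSummary:
    """Credible summaries of partner counts, next to the raw observed counts."""

    animals: pd.DataFrame  # per observed animal species: NP_j summaries
    plants: pd.DataFrame   # per plant species: NA_k summaries
    includes_augmented: bool = True  # NA_k sums run over the supercommunity


@dataclass
class RichnessSummary:
    """Posterior summary of total species richness N."""

    mean: float
    median: float
    ci_lower: float
    ci_upper: float
    supercommunity_size: int
    n_observed: int
    at_ceiling: bool  # upper bound touches S: supercommunity too small

    def __str__(self) -> str:
        s = (f"richness N = {self.mean:.0f} ({self.ci_lower:.0f}, {self.ci_upper:.0f}); "
             f"observed {self.n_observed} of supercommunity {self.supercommunity_size}")
        if self.at_ceiling:
            s += " [WARNING: interval touches the supercommunity ceiling]"
        return s


class ZIPNMixtureResults:
    """Thinned posterior draws across chains, with convergence diagnostics.

    ``draws`` maps parameter names to arrays of shape
    ``(n_chains, n_saved, *param_shape)``.
    """

    def __init__(self, model: ZIPNMixtureModel, config: MCMCConfig,
                 draws: dict[str, np.ndarray], final_states=None, extended: int = 0):
        self.model = model
        self.dataset = model.dataset
        self.config = config
        self.draws = draws
        self.final_states = final_states or []
        self.extended = extended
        self._diagnostics: pd.DataFrame | None = None

    # -- basic access --------------------------------------------------------
    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains: shape (n_chains * n_saved, ...)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.draws["alpha0"].shape[0] * self.draws["alpha0"].shape[1]

    # -- diagnostics ---------------------------------------------------------
    @property
    def diagnostics(self) -> pd.DataFrame:
        """Rhat and effective sample size per monitored scalar parameter."""
        if self._diagnostics is None:
            rows = []
            scalars = ["alpha0", "beta0", "sigma_alpha", "sigma_beta", "Omega", "N"]
            for name in scalars:
                d = self.draws[name].astype(float)
                rows.append((name, rhat(d), _ess(d)))
            # per-element diagnostics for the abundance effects
            b1 = self.draws["beta1"]
            for j in range(b1.shape[-1]):
                d = b1[..., j]
                rows.append((f"beta1[{j}]", rhat(d), _ess(d)))
            self._diagnostics = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
        return self._diagnostics

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())

    @property
    def converged(self) -> bool:
        return self.max_rhat < self.config.rhat_threshold

    # -- presentation --------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior table for the community-level parameters."""
        rows = []
        for name in ["alpha0", "beta0", "sigma_alpha", "sigma_beta", "Omega", "N"]:
            x = self.stacked(name).astype(float)
            q = np.quantile(x, [0.025, 0.5, 0.975])
            rows.append({
                "parameter": name, "mean": x.mean(), "sd": x.std(ddof=1),
                "q2.5": q[0], "median": q[1], "q97.5": q[2],
                "rhat": float(self.diagnostics.set_index("parameter").loc[name, "rhat"]),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def __repr__(self) -> str:
        ds = self.dataset
        return (f"<ZIPNMixtureResults: {ds.n_individuals} individuals x "
                f"{ds.supercommunity_size} species ({ds.n_observed} observed), "
                f"{self.n_draws} draws, max Rhat {self.max_rhat:.3f}>")

    # -- derived quantities ---------------------------------------------------
    def partner_counts(self) -> PartnerCountSummary:
        return partner_counts(self)

    def species_richness(self) -> RichnessSummary:
        return species_richness(self)

    def detection_completeness(self) -> tuple[float, float]:
        return detection_completeness(self.dataset.n_observed, self.species_richness())

    def posterior_predictive_networks(self, n_networks: int = 1000, rng=None,
                                      mode: str = "expected",
                                      effort=None) -> list[SpeciesMatrix]:
        return posterior_predictive_networks(self, n_networks, rng, mode=mode,
                                             effort=effort)

    def posterior_mean_theta(self) -> np.ndarray:
        """Posterior mean of the pair-interaction indicators (K, S)."""
        return self.stacked("theta").mean(axis=0)

    def plot_traces(self, params=("alpha0", "beta0", "sigma_alpha", "sigma_beta", "N"),
                    path=None):
        """Minimal diagnostic trace plots (one panel per parameter)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(len(params), 1, figsize=(7, 2 * len(params)),
                                 squeeze=False)
        for ax, name in zip(axes[:, 0], params):
            for c in range(self.draws[name].shape[0]):
                ax.plot(self.draws[name][c].astype(float), lw=0.6)
            ax.set_ylabel(name)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=100)
            plt.close(fig)
        return fig


#: alias kept for the domain vocabulary: the results object *is* the
#: container of thinned posterior samples with diagnostics
PosteriorSamples = ZIPNMixtureResults


# ---------------------------------------------------------------------------
# derived-quantity functions


def _quantile_frame(draws: np.ndarray, labels, observed) -> pd.DataFrame:
    cols = {k: np.quantile(draws, q, axis=0) for k, q in _QUANTS.items()}
    df = pd.DataFrame(cols, index=labels)
    df["observed"] = observed
    return df


def partner_counts(results: ZIPNMixtureResults) -> PartnerCountSummary:
    """Posterior partner-count summaries NP_j and NA_k.

    Per draw, NP_j = sum_k theta_kj and NA_k = sum_j theta_kj.  NA_k sums
    over the whole supercommunity (undetected species contribute); NP_j is
    reported for observed animal species only, since augmented species are
    exchangeable and carry no identity.
    """
    ds = results.dataset
    theta = results.stacked("theta")            # (D, K, S)
    NP = theta.sum(axis=1)                      # (D, S)
    NA = theta.sum(axis=2)                      # (D, K)
    obs_T = ds.species_totals() > 0
    animals = _quantile_frame(
        NP[:, : ds.n_observed],
        ds.animal_labels[: ds.n_observed],
        obs_T.sum(axis=0)[: ds.n_observed],
    )
    plants = _quantile_frame(NA, ds.plant_labels, obs_T.sum(axis=1))
    return PartnerCountSummary(animals=animals, plants=plants, includes_augmented=True)


def species_richness(results: ZIPNMixtureResults) -> RichnessSummary:
    """Posterior richness N = sum_j omega_j over the supercommunity."""
    N = results.stacked("N").astype(float)
    lo, med, hi = np.quantile(N, [0.025, 0.5, 0.975])
    S = results.dataset.supercommunity_size
    return RichnessSummary(
        mean=float(N.mean()), median=float(med), ci_lower=float(lo),
        ci_upper=float(hi), supercommunity_size=S,
        n_observed=results.dataset.n_observed, at_ceiling=bool(hi >= S),
    )


def detection_completeness(n_observed: int, richness: RichnessSummary) -> tuple[float, float]:
    """Percentage bounds on sampling completeness from the richness interval.

    The low bound is 100·n / (upper 95% richness bound); the high bound is
    100·n / (lower bound), clamped to 100% when the interval undershoots the
    observed richness.
    """
    if n_observed < 1:
        raise ValueError("n_observed must be >= 1")
    low = 100.0 * n_observed / richness.ci_upper
    high = 100.0 if richness.ci_lower < n_observed else 100.0 * n_observed / richness.ci_lower
    return low, min(high, 100.0)


def posterior_predictive_networks(results: ZIPNMixtureResults, n_networks: int = 1000,
                                  rng=None, mode: str = "expected",
                                  effort=None) -> list[SpeciesMatrix]:
    """Species-level networks generated from posterior draws.

    For each of ``n_networks`` uniformly selected posterior draws the weight
    of cell (k, j) is theta_kj * lambda_j * effort_k, with ``effort_k`` the
    number of individuals of plant k (the dataset's own effort by default).
    ``mode="realized"`` additionally Poisson-realises each cell.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if mode not in ("expected", "realized"):
        raise ValueError("mode must be 'expected' or 'realized'")
    rng = np.random.default_rng(rng)
    ds = results.dataset
    theta = results.stacked("theta")
    lam = results.stacked("lam")
    n_avail = theta.shape[0]
    if n_networks > n_avail:
        warnings.warn(
            f"requested {n_networks} networks from {n_avail} draws; "
            "sampling with replacement", stacklevel=2)
        pick = rng.integers(0, n_avail, size=n_networks)
    else:
        pick = rng.choice(n_avail, size=n_networks, replace=False)
    if effort is None:
        effort = ds.individuals_per_plant()
    effort = np.broadcast_to(np.asarray(effort, dtype=float),
                             (ds.n_plant_species,))
    nets = []
    for d in pick:
        w = theta[d] * lam[d][None, :] * effort[:, None]
        if mode == "realized":
            w = rng.poisson(w).astype(float)
        nets.append(SpeciesMatrix(weights=w, row_labels=list(ds.plant_labels),
                                  col_labels=list(ds.animal_labels)))
    return nets
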