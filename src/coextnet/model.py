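"""Hierarchical zero-inflated Poisson N-mixture model for interaction counts.

The observation model treats the count of animal species j on plant
individual i (of plant species k) as

    Y_ij ~ Poisson(theta_kj * lambda_j),

where theta_kj is a latent binary indicator of whether the species pair
interacts at all (the zero-inflation component) and lambda_j is the expected
per-observation abundance of animal j.  Both latents have their own
regressions:

    log(lambda_j) = beta0 + beta1_j,          beta1_j ~ N(0, sigma_beta^2)
    theta_kj ~ Bernoulli(Theta_kj),
    Theta_kj = omega_j * invlogit(psi_kj),    psi_kj = alpha0 + alpha1_kj,
    alpha1_kj ~ N(0, sigma_alpha^2),
    omega_j ~ Bernoulli(Omega),               Omega ~ U(0, 1).

omega_j marks whether animal j is present in the community at all; summed
over a zero-augmented "supercommunity" it yields the total species richness
N.  Priors: half-Cauchy(0, 10) on both standard deviations, N(0, 10^2) on
the intercepts.

Inference is Metropolis-within-Gibbs: theta, omega and Omega have exact full
conditionals (omega is updated with theta collapsed out column-wise), the
continuous blocks use adaptive random-walk Metropolis with the adaptation
frozen after burn-in.

The public surface follows the statsmodels convention: build a
:class:`ZIPNMixtureModel` from an :class:`~coextnet.data.InteractionDataset`
and call :meth:`~ZIPNMixtureModel.fit` to obtain a
:class:`~coextnet.results.ZIPNMixtureResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln
from scipy.stats import halfcauchy

from .data import InteractionDataset, augment_dataset, from_long_frame

__all__ = [
    "ModelState",
    "MCMCConfig",
    "ZIPNMixtureModel",
    "log_likelihood",
    "log_prior",
    "log_joint",
    "compute_abundance",
    "compute_interaction_prob",
    "fit_mcmc",
    "rhat",
]

_EPS = 1e-12
_INTERCEPT_SD = 10.0
_SIGMA_SCALE = 10.0


def compute_abundance(beta0: float, beta1: np.ndarray) -> np.ndarray:
    """Expected per-observation abundance lambda_j = exp(beta0 + beta1_j)."""
    return np.exp(beta0 + np.asarray(beta1, dtype=float))


def compute_interaction_prob(psi: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Interaction probability Theta_kj = omega_j * invlogit(psi_kj).

    A species absent from the community (omega_j = 0) cannot interact, so
    its column is exactly zero.
    """
    return np.asarray(omega, dtype=float)[None, :] * expit(np.asarray(psi, dtype=float))


@dataclass
class ModelState:
    """One complete assignment of latent variables and parameters."""

    theta: np.ndarray       # (K, S) binary pair-interaction indicators
    omega: np.ndarray       # (S,) binary availability indicators
    Omega: float            # community-level availability probability
    alpha0: float
    alpha1: np.ndarray      # (K, S) pair effects
    sigma_alpha: float
    beta0: float
    beta1: np.ndarray       # (S,) species abundance effects
    sigma_beta: float

    @property
    def psi(self) -> np.ndarray:
        return self.alpha0 + self.alpha1

    @property
    def Theta(self) -> np.ndarray:
        return compute_interaction_prob(self.psi, self.omega)

    @property
    def lam(self) -> np.ndarray:
        return compute_abundance(self.beta0, self.beta1)


@dataclass
class MCMCConfig:
    """Chain layout and bookkeeping for the sampler.

    Defaults follow the simulation protocol of the study design (four
    chains, thinning 100, convergence judged at Rhat < 1.1); ``burn_in``
    defaults to 10% of ``n_iter``.
    """

    n_chains: int = 4
    n_iter: int = 200_000
    burn_in: int | None = None
    thin: int = 100
    seed: int = 0
    rhat_threshold: float = 1.1
    save_pair_effects: bool = True
    prior_only: bool = False

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.n_iter // 10
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


# ---------------------------------------------------------------------------
# densities


def log_likelihood(ds: InteractionDataset, state: ModelState) -> float:
    """Sum of Poisson log-densities of the counts given the state.

    Convention for the structural zero: Poisson(y | 0) is 1 when y = 0 and 0
    otherwise, so a pair with theta = 0 but a positive count contributes
    -inf (an impossible configuration, not an exception).
    """
    lam = state.lam
    mu = state.theta[ds.plant_species_of] * lam[None, :]
    y = ds.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(
            mu > 0,
            y * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(y + 1),
            np.where(y == 0, 0.0, -np.inf),
        )
    return float(ll.sum())


def log_prior(state: ModelState, *, intercept_sd: float = _INTERCEPT_SD,
              sigma_scale: float = _SIGMA_SCALE) -> float:
    """Joint log prior of the continuous parameters and omega."""
    if state.sigma_alpha <= 0 or state.sigma_beta <= 0:
        return -np.inf
    if not (0.0 <= state.Omega <= 1.0):
        return -np.inf
    lp = 0.0
    for sigma in (state.sigma_alpha, state.sigma_beta):
        lp += halfcauchy.logpdf(sigma, scale=sigma_scale)
    for x in (state.alpha0, state.beta0):
        lp += -0.5 * (x / intercept_sd) ** 2 - np.log(intercept_sd) - 0.5 * np.log(2 * np.pi)
    a = state.alpha1.ravel()
    lp += (-0.5 * (a / state.sigma_alpha) ** 2
           - np.log(state.sigma_alpha) - 0.5 * np.log(2 * np.pi)).sum()
    b = state.beta1
    lp += (-0.5 * (b / state.sigma_beta) ** 2
           - np.log(state.sigma_beta) - 0.5 * np.log(2 * np.pi)).sum()
    n1 = int(state.omega.sum())
    n0 = state.omega.size - n1
    Om = np.clip(state.Omega, _EPS, 1 - _EPS)
    lp += n1 * np.log(Om) + n0 * np.log1p(-Om)
    return float(lp)


def log_joint(ds: InteractionDataset, state: ModelState) -> float:
    """Full joint log density including the theta | Theta layer."""
    Theta = np.clip(state.Theta, 0.0, 1.0)
    t = state.theta
    with np.errstate(divide="ignore"):
        lt = np.where(t == 1, np.log(np.clip(Theta, _EPS, None)),
                      np.log1p(-np.clip(Theta, None, 1 - _EPS)))
    # exact structural cases: Theta=0 forces theta=0 with probability one
    lt = np.where((Theta == 0) & (t == 0), 0.0, lt)
    lt = np.where((Theta == 0) & (t == 1), -np.inf, lt)
    return log_likelihood(ds, state) + float(lt.sum()) + log_prior(state)


# ---------------------------------------------------------------------------
# the model object


class ZIPNMixtureModel:
    """Zero-inflated Poisson N-mixture model bound to a dataset.

    Parameters
    ----------
    dataset
        Individual-level interaction counts, typically already augmented to
        the desired supercommunity size (see
        :func:`coextnet.data.augment_dataset`).
    """

    def __init__(self, dataset: InteractionDataset):
        dataset.validate()
        if dataset.supercommunity_size < dataset.n_observed:
            raise ValueError("supercommunity smaller than the observed community")
        self.dataset = dataset
        self.K = dataset.n_plant_species
        self.S = dataset.supercommunity_size
        # sufficient statistics: pair totals, individuals per plant species
        self.T = dataset.species_totals()           # (K, S)
        self.n_k = dataset.individuals_per_plant()  # (K,)
        self.obs_any = self.T.any(axis=0)           # (S,) species with data
        self.C = self.T.sum(axis=0).astype(float)   # (S,) count totals

    @classmethod
    def from_dataframe(cls, df, *, m_augment: int = 0) -> "ZIPNMixtureModel":
        """Build from a long-format table, optionally augmenting."""
        ds = from_long_frame(df)
        if m_augment:
            ds = augment_dataset(ds, m_augment)
        return cls(ds)

    # -- densities bound to the data ----------------------------------------
    def loglike(self, state: ModelState) -> float:
        return log_likelihood(self.dataset, state)

    def logprior(self, state: ModelState) -> float:
        return log_prior(state)

    def logjoint(self, state: ModelState) -> float:
        return log_joint(self.dataset, state)

    # -- initialisation ------------------------------------------------------
    def _initial_state(self, rng: np.random.Generator) -> ModelState:
        K, S = self.K, self.S
        rate = self.C.sum() / max(self.n_k.sum(), 1)
        beta0 = float(np.log(rate + 1e-3) + 0.2 * rng.standard_normal())
        omega = np.where(self.obs_any, 1, (rng.random(S) < 0.5)).astype(np.int8)
        theta = np.where(self.T > 0, 1,
                         (rng.random((K, S)) < 0.3) & (omega[None, :] == 1)).astype(np.int8)
        return ModelState(
            theta=theta,
            omega=omega,
            Omega=float((self.obs_any.sum() + 1) / (S + 2)),
            alpha0=float(rng.normal(0, 1)),
            alpha1=0.1 * rng.standard_normal((K, S)),
            sigma_alpha=float(0.5 + abs(rng.normal(0, 1))),
            beta0=beta0,
            beta1=0.1 * rng.standard_normal(S),
            sigma_beta=float(0.5 + abs(rng.normal(0, 1))),
        )

    # -- sampler -------------------------------------------------------------
    def _run_chain(self, cfg: MCMCConfig, rng: np.random.Generator,
                   state: ModelState | None = None,
                   collect_burnin: bool = True):
        """One MCMC chain; returns (saved draw dict, final state)."""
        K, S = self.K, self.S
        T, n_k, obs_any, C = self.T, self.n_k, self.obs_any, self.C
        if cfg.prior_only:
            # disable every likelihood factor: the chain then targets the
            # joint prior, which is useful for validating the sampler
            T = np.zeros_like(T)
            n_k = np.zeros_like(n_k)
            obs_any = np.zeros(S, dtype=bool)
            C = np.zeros(S)
        positive = T > 0

        st = state if state is not None else self._initial_state(rng)
        theta = st.theta.astype(np.int8).copy()
        omega = st.omega.astype(np.int8).copy()
        Omega = float(st.Omega)
        alpha0, alpha1 = float(st.alpha0), st.alpha1.astype(float).copy()
        lsig_a = float(np.log(st.sigma_alpha))
        beta0, beta1 = float(st.beta0), st.beta1.astype(float).copy()
        lsig_b = float(np.log(st.sigma_beta))

        # adaptive proposal scales (frozen after burn-in)
        scales = {"alpha1": 0.8, "alpha0": 0.3, "lsig_a": 0.4,
                  "beta1": 0.4, "beta0": 0.2, "lsig_b": 0.4,
                  "shift_a": 1.0, "shift_b": 0.5, "scale_a": 0.3}
        acc = dict.fromkeys(scales, 0.0)
        tries = dict.fromkeys(scales, 0.0)
        targets = {"alpha1": 0.4, "alpha0": 0.35, "lsig_a": 0.35,
                   "beta1": 0.4, "beta0": 0.35, "lsig_b": 0.35,
                   "shift_a": 0.35, "shift_b": 0.35, "scale_a": 0.35}

        n_saved = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
        out = {
            "alpha0": np.empty(n_saved), "beta0": np.empty(n_saved),
            "sigma_alpha": np.empty(n_saved), "sigma_beta": np.empty(n_saved),
            "Omega": np.empty(n_saved), "N": np.empty(n_saved, dtype=np.int64),
            "beta1": np.empty((n_saved, S)), "lam": np.empty((n_saved, S)),
            "theta": np.empty((n_saved, K, S), dtype=np.int8),
            "omega": np.empty((n_saved, S), dtype=np.int8),
        }
        if cfg.save_pair_effects:
            out["alpha1"] = np.empty((n_saved, K, S))

        isd2 = _INTERCEPT_SD ** 2
        idx = 0
        for it in range(cfg.n_iter):
            adapting = collect_burnin and it < cfg.burn_in
            lam = np.exp(np.minimum(beta0 + beta1, 700.0))    # (S,)
            q = np.clip(expit(alpha0 + alpha1), _EPS, 1 - _EPS)  # (K, S)
            E = np.exp(-np.outer(n_k, lam))                   # (K, S)
            M = q * E + (1.0 - q)

            # --- omega: collapsed Gibbs (theta marginalised per column) ---
            logL1 = np.log(M).sum(axis=0)                     # (S,)
            Om = np.clip(Omega, _EPS, 1 - _EPS)
            p1 = expit(np.log(Om) - np.log1p(-Om) + logL1)
            omega = np.where(obs_any, 1,
                             (rng.random(S) < p1)).astype(np.int8)

            # --- theta | omega: exact Gibbs ---
            p_theta = np.where(omega[None, :] == 1, q * E / M, 0.0)
            theta = np.where(positive, 1,
                             (rng.random((K, S)) < p_theta)).astype(np.int8)

            # --- Omega: conjugate Beta update ---
            n1 = int(omega.sum())
            Omega = float(rng.beta(1 + n1, 1 + S - n1))

            # --- alpha1: per-cell MH where active, prior draw elsewhere ---
            sig_a = np.exp(lsig_a)
            active = np.broadcast_to(omega == 1, (K, S))
            prop = alpha1 + scales["alpha1"] * rng.standard_normal((K, S))
            qp = np.clip(expit(alpha0 + prop), _EPS, 1 - _EPS)
            ll_new = np.where(theta == 1, np.log(qp), np.log1p(-qp))
            ll_old = np.where(theta == 1, np.log(q), np.log1p(-q))
            dlp = (prop ** 2 - alpha1 ** 2) / (-2 * sig_a ** 2)
            accept = np.log(rng.random((K, S))) < (ll_new - ll_old + dlp)
            take = active & accept
            alpha1 = np.where(take, prop, alpha1)
            alpha1 = np.where(~active, sig_a * rng.standard_normal((K, S)), alpha1)
            if adapting:
                acc["alpha1"] += take.sum() / max(active.sum(), 1)
                tries["alpha1"] += 1

            # --- alpha0: scalar MH over active cells ---
            q = np.clip(expit(alpha0 + alpha1), _EPS, 1 - _EPS)
            prop0 = alpha0 + scales["alpha0"] * rng.standard_normal()
            qp = np.clip(expit(prop0 + alpha1), _EPS, 1 - _EPS)
            w_active = (omega == 1)[None, :]
            ll_new = (np.where(theta == 1, np.log(qp), np.log1p(-qp)) * w_active).sum()
            ll_old = (np.where(theta == 1, np.log(q), np.log1p(-q)) * w_active).sum()
            d = ll_new - ll_old + (alpha0 ** 2 - prop0 ** 2) / (2 * isd2)
            tries["alpha0"] += adapting
            if np.log(rng.random()) < d:
                alpha0 = prop0
                acc["alpha0"] += adapting

            # --- sigma_alpha: MH on log scale, half-Cauchy prior ---
            ssq = float((alpha1 ** 2).sum())
            lp_cur = self._lsig_target(lsig_a, ssq, K * S)
            propl = lsig_a + scales["lsig_a"] * rng.standard_normal()
            tries["lsig_a"] += adapting
            if np.log(rng.random()) < self._lsig_target(propl, ssq, K * S) - lp_cur:
                lsig_a = propl
                acc["lsig_a"] += adapting

            # --- beta1: per-species MH where exposed, prior draw elsewhere ---
            sig_b = np.exp(lsig_b)
            A = theta.T.astype(float) @ n_k                   # (S,) exposure
            exposed = A > 0
            lam = np.exp(np.minimum(beta0 + beta1, 700.0))
            propb = beta1 + scales["beta1"] * rng.standard_normal(S)
            lam_p = np.exp(np.minimum(beta0 + propb, 700.0))
            d = (np.where(exposed, -A * (lam_p - lam), 0.0) + C * (propb - beta1)
                 + (beta1 ** 2 - propb ** 2) / (2 * sig_b ** 2))
            accept = np.log(rng.random(S)) < d
            take = exposed & accept
            beta1 = np.where(take, propb, beta1)
            beta1 = np.where(~exposed, sig_b * rng.standard_normal(S), beta1)
            if adapting:
                acc["beta1"] += take.sum() / max(exposed.sum(), 1)
                tries["beta1"] += 1

            # --- beta0: scalar MH ---
            lam = np.exp(np.minimum(beta0 + beta1, 700.0))
            prop0 = beta0 + scales["beta0"] * rng.standard_normal()
            lam_p = np.exp(np.minimum(prop0 + beta1, 700.0))
            d = (-(A[exposed] * (lam_p[exposed] - lam[exposed])).sum()
                 + C.sum() * (prop0 - beta0)
                 + (beta0 ** 2 - prop0 ** 2) / (2 * isd2))
            tries["beta0"] += adapting
            if np.log(rng.random()) < d:
                beta0 = prop0
                acc["beta0"] += adapting

            # --- coordinated rescale of (sigma_alpha, alpha1) ---
            # the half-Cauchy tail lets sigma_alpha grow with alpha1 in step;
            # a joint log-scale move explores that ridge.  MH ratio: pair
            # likelihood at the rescaled effects, half-Cauchy prior change,
            # and a net +log(c) from the Gaussian layer and the Jacobian.
            lc = scales["scale_a"] * rng.standard_normal()
            c = np.exp(lc)
            a_new = c * alpha1
            qn = np.clip(expit(alpha0 + a_new), _EPS, 1 - _EPS)
            qo = np.clip(expit(alpha0 + alpha1), _EPS, 1 - _EPS)
            w_active = (omega == 1)[None, :]
            ll_new = (np.where(theta == 1, np.log(qn), np.log1p(-qn)) * w_active).sum()
            ll_old = (np.where(theta == 1, np.log(qo), np.log1p(-qo)) * w_active).sum()
            sig_a = np.exp(lsig_a)
            d = (ll_new - ll_old + lc
                 + halfcauchy.logpdf(c * sig_a, scale=_SIGMA_SCALE)
                 - halfcauchy.logpdf(sig_a, scale=_SIGMA_SCALE))
            tries["scale_a"] += adapting
            if np.log(rng.random()) < d:
                alpha1 = a_new
                lsig_a += lc
                acc["scale_a"] += adapting

            # --- translation moves along the intercept/random-effect ridge ---
            # shifting the intercept and counter-shifting every random effect
            # leaves the likelihood invariant; only the priors change.  This
            # is an exact MH move that decorrelates alpha0 from alpha1 (and
            # beta0 from beta1), whose sum is all the likelihood identifies.
            sig_a = np.exp(lsig_a)
            delta = scales["shift_a"] * rng.standard_normal()
            d = ((alpha0 ** 2 - (alpha0 + delta) ** 2) / (2 * isd2)
                 + (float((alpha1 ** 2).sum())
                    - float(((alpha1 - delta) ** 2).sum())) / (2 * sig_a ** 2))
            tries["shift_a"] += adapting
            if np.log(rng.random()) < d:
                alpha0 += delta
                alpha1 = alpha1 - delta
                acc["shift_a"] += adapting

            sig_b = np.exp(lsig_b)
            delta = scales["shift_b"] * rng.standard_normal()
            d = ((beta0 ** 2 - (beta0 + delta) ** 2) / (2 * isd2)
                 + (float((beta1 ** 2).sum())
                    - float(((beta1 - delta) ** 2).sum())) / (2 * sig_b ** 2))
            tries["shift_b"] += adapting
            if np.log(rng.random()) < d:
                beta0 += delta
                beta1 = beta1 - delta
                acc["shift_b"] += adapting

            # --- sigma_beta ---
            ssq = float((beta1 ** 2).sum())
            lp_cur = self._lsig_target(lsig_b, ssq, S)
            propl = lsig_b + scales["lsig_b"] * rng.standard_normal()
            tries["lsig_b"] += adapting
            if np.log(rng.random()) < self._lsig_target(propl, ssq, S) - lp_cur:
                lsig_b = propl
                acc["lsig_b"] += adapting

            # --- adaptation (burn-in only) ---
            if adapting and (it + 1) % 100 == 0:
                for key in scales:
                    if tries[key] > 0:
                        rate = acc[key] / tries[key]
                        scales[key] *= float(np.exp(0.6 * (rate - targets[key])))
                        scales[key] = float(np.clip(scales[key], 1e-3, 10.0))
                        acc[key] = tries[key] = 0.0

            # --- save ---
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                out["alpha0"][idx] = alpha0
                out["beta0"][idx] = beta0
                out["sigma_alpha"][idx] = np.exp(lsig_a)
                out["sigma_beta"][idx] = np.exp(lsig_b)
                out["Omega"][idx] = Omega
                out["N"][idx] = int(omega.sum())
                out["beta1"][idx] = beta1
                out["lam"][idx] = np.exp(np.minimum(beta0 + beta1, 700.0))
                out["theta"][idx] = theta
                out["omega"][idx] = omega
                if cfg.save_pair_effects:
                    out["alpha1"][idx] = alpha1
                idx += 1

        final = ModelState(
            theta=theta, omega=omega, Omega=Omega,
            alpha0=alpha0, alpha1=alpha1, sigma_alpha=float(np.exp(lsig_a)),
            beta0=beta0, beta1=beta1, sigma_beta=float(np.exp(lsig_b)),
        )
        for k in out:
            out[k] = out[k][:idx]
        return out, final

    @staticmethod
    def _lsig_target(lsig: float, ssq: float, n: int) -> float:
        """Log target for log(sigma): Gaussian bulk + half-Cauchy prior + Jacobian."""
        sig = np.exp(lsig)
        return (-n * lsig - ssq / (2 * sig ** 2)
                + halfcauchy.logpdf(sig, scale=_SIGMA_SCALE) + lsig)

    def fit(self, n_chains: int = 4, n_iter: int = 200_000, burn_in: int | None = None,
            thin: int = 100, seed: int = 0, rhat_threshold: float = 1.1,
            save_pair_effects: bool = True, prior_only: bool = False,
            config: MCMCConfig | None = None):
        """Run the MCMC and return a :class:`~coextnet.results.ZIPNMixtureResults`.

        Two calls with the same configuration and seed produce identical
        draws.  An all-zero dataset is legal but yields a prior-dominated
        posterior (a warning is emitted).
        """
        from .results import ZIPNMixtureResults

        cfg = config or MCMCConfig(
            n_chains=n_chains, n_iter=n_iter, burn_in=burn_in, thin=thin,
            seed=seed, rhat_threshold=rhat_threshold,
            save_pair_effects=save_pair_effects, prior_only=prior_only,
        )
        if not cfg.prior_only and not self.obs_any.any():
            warnings.warn("dataset has no nonzero counts; posterior is prior-dominated",
                          stacklevel=2)
        streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        chains, finals = [], []
        for s in streams:
            draws, final = self._run_chain(cfg, np.random.default_rng(s))
            chains.append(draws)
            finals.append(final)
        draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
        return ZIPNMixtureResults(self, cfg, draws, final_states=finals)

    def continue_fit(self, results, n_iter: int):
        """Extend converged-or-not chains by ``n_iter`` iterations (no burn-in).

        Mirrors the protocol of updating unconverged chains for a further
        block of iterations; the extension reuses the stored final states and
        appends the newly thinned draws.
        """
        from .results import ZIPNMixtureResults

        cfg = results.config
        ext = MCMCConfig(
            n_chains=cfg.n_chains, n_iter=n_iter, burn_in=0, thin=cfg.thin,
            seed=cfg.seed + 1_000_003, rhat_threshold=cfg.rhat_threshold,
            save_pair_effects=cfg.save_pair_effects,
        )
        streams = np.random.SeedSequence(ext.seed).spawn(cfg.n_chains)
        chains, finals = [], []
        for s, state in zip(streams, results.final_states):
            draws, final = self._run_chain(ext, np.random.default_rng(s),
                                           state=state, collect_burnin=False)
            chains.append(draws)
            finals.append(final)
        merged = {
            k: np.concatenate([results.draws[k],
                               np.stack([c[k] for c in chains])], axis=1)
            for k in results.draws
        }
        return ZIPNMixtureResults(self, cfg, merged, final_states=finals,
                                  extended=results.extended + 1)


def fit_mcmc(ds: InteractionDataset, cfg: MCMCConfig):
    """Functional entry point: fit the model to a dataset with ``cfg``."""
    return ZIPNMixtureModel(ds).fit(config=cfg)


# ---------------------------------------------------------------------------
# convergence diagnostic


def rhat(draws: np.ndarray) -> float:
    """Potential scale reduction factor from between/within chain variance.

    ``draws`` has shape (n_chains, n_draws).  Computes
    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance and
    B/n the variance of the chain means.  Degenerate chains with zero
    within-chain variance return 1.0 when the chain means agree and +inf
    otherwise.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("rhat needs >= 2 chains with >= 2 draws each")
    n = x.shape[1]
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0 if np.allclose(means, means[0]) else float("inf")
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))
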