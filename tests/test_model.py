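import numpy as np
import pytest

from coextnet.data import InteractionDataset, augment_dataset
from coextnet.model import (
    MCMCConfig,
    ModelState,
    ZIPNMixtureModel,
    compute_abundance,
    compute_interaction_prob,
    fit_mcmc,
    log_joint,
    log_likelihood,
    log_prior,
    rhat,
)


def single_cell_dataset(y: int) -> InteractionDataset:
    return InteractionDataset(
        counts=np.array([[y]]),
        plant_species_of=np.array([0]),
        plant_labels=["P0"], animal_labels=["a0"], individual_labels=["i0"],
        n_observed=1,
    )


def single_cell_state(theta: int, lam: float) -> ModelState:
    return ModelState(
        theta=np.array([[theta]], dtype=np.int8),
        omega=np.array([1], dtype=np.int8), Omega=0.5,
        alpha0=0.0, alpha1=np.zeros((1, 1)), sigma_alpha=1.0,
        beta0=float(np.log(lam)) if lam > 0 else 0.0,
        beta1=np.zeros(1), sigma_beta=1.0,
    )


class TestLogLikelihood:
    @pytest.mark.parametrize("theta,lam,y,expected", [
        (0, 1.0, 0, 0.0),                      # Poisson(0 | 0) = 1
        (1, 1.0, 0, -1.0),                     # log e^-1
        (1, 2.0, 3, np.log(8 * np.exp(-2) / 6)),  # hand-evaluated pmf, -1.7123
    ])
    def test_single_cell_values(self, theta, lam, y, expected):
        ll = log_likelihood(single_cell_dataset(y), single_cell_state(theta, lam))
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_structural_impossibility_is_minus_infinity(self):
        # theta = 0 but a positive count: impossible, not an exception
        ll = log_likelihood(single_cell_dataset(3), single_cell_state(0, 1.0))
        assert ll == -np.inf


class TestDeterministicMaps:
    def test_abundance_identity(self):
        assert compute_abundance(0.0, np.zeros(3)).tolist() == [1.0, 1.0, 1.0]

    def test_low_abundance_rate(self):
        lam = compute_abundance(-3.0, np.zeros(1))
        assert lam[0] == pytest.approx(0.0498, abs=5e-4)
        assert 1 / lam[0] == pytest.approx(20, rel=0.005)

    def test_exponentiation(self):
        assert compute_abundance(1.0, np.ones(1))[0] == pytest.approx(np.e ** 2)

    def test_absent_species_cannot_interact(self):
        Theta = compute_interaction_prob(np.array([[3.0], [1.0]]), np.array([0]))
        assert not Theta.any()

    def test_inverse_logit_values(self):
        assert compute_interaction_prob(np.zeros((1, 1)), np.ones(1))[0, 0] == 0.5
        # the high-interaction mean corresponds to ~80% of pairs interacting
        p = compute_interaction_prob(np.full((1, 1), 1.5), np.ones(1))[0, 0]
        assert p == pytest.approx(0.8176, abs=1e-4)


class TestLogPrior:
    def base_state(self, **kw):
        defaults = dict(
            theta=np.zeros((1, 2), dtype=np.int8),
            omega=np.ones(2, dtype=np.int8), Omega=0.5,
            alpha0=0.0, alpha1=np.zeros((1, 2)), sigma_alpha=1.0,
            beta0=0.0, beta1=np.zeros(2), sigma_beta=1.0,
        )
        defaults.update(kw)
        return ModelState(**defaults)

    def test_half_cauchy_density_at_origin(self):
        # the half-Cauchy(0, 10) log density at sigma -> 0+ is log(2/(10 pi))
        lp_small = log_prior(self.base_state(sigma_alpha=1e-12))
        lp_one = log_prior(self.base_state(sigma_alpha=1.0))
        from scipy.stats import halfcauchy
        assert halfcauchy.logpdf(0.0, scale=10) == pytest.approx(-2.7541, abs=1e-4)
        # moving sigma_alpha changes both its prior and the alpha1 layer;
        # with alpha1 = 0 the Gaussian layer contributes -sum(log sigma) - c
        assert np.isfinite(lp_one)
        assert lp_small > lp_one  # at alpha1=0, tiny sigma concentrates mass

    def test_support_violations(self):
        assert log_prior(self.base_state(Omega=1.5)) == -np.inf
        assert log_prior(self.base_state(sigma_beta=-1.0)) == -np.inf
        assert log_prior(self.base_state(sigma_beta=0.0)) == -np.inf

    def test_standard_normal_effects_term(self):
        # moving one beta1 from 0 to 1 with sigma_beta = 1 costs exactly 1/2
        lp0 = log_prior(self.base_state())
        lp1 = log_prior(self.base_state(beta1=np.array([1.0, 0.0])))
        assert lp0 - lp1 == pytest.approx(0.5)

    def test_joint_density_finite_for_consistent_state(self):
        ds = single_cell_dataset(2)
        st = single_cell_state(1, 1.5)
        assert np.isfinite(log_joint(ds, st))
        # inconsistent: theta = 0 under a positive count
        assert log_joint(ds, single_cell_state(0, 1.5)) == -np.inf


class TestRhat:
    def test_identical_chains(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(2000)
        assert rhat(np.stack([chain, chain])) == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_constant_chains_diverge(self):
        x = np.stack([np.zeros(100), np.ones(100)])
        assert rhat(x) == np.inf

    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 10_000))
        assert abs(rhat(x) - 1.0) < 0.01

    def test_requires_multiple_chains(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestSampler:
    def test_same_seed_identical_draws(self, tiny_fit):
        model = tiny_fit["model"]
        res2 = model.fit(n_chains=2, n_iter=2000, thin=10, seed=4)
        for name, arr in tiny_fit["results"].draws.items():
            assert np.array_equal(arr, res2.draws[name]), name

    def test_config_entry_point_matches_method(self, tiny_fit):
        cfg = MCMCConfig(n_chains=2, n_iter=2000, thin=10, seed=4)
        res = fit_mcmc(tiny_fit["observed"], cfg)
        assert np.array_equal(res.draws["N"], tiny_fit["results"].draws["N"])

    def test_observed_pairs_force_theta_one(self, tiny_fit):
        ds = tiny_fit["observed"]
        T = ds.species_totals()
        theta = tiny_fit["results"].draws["theta"]  # (chains, draws, K, S)
        assert (theta[:, :, T > 0] == 1).all()

    def test_observed_species_force_omega_one(self, tiny_fit):
        ds = tiny_fit["observed"]
        omega = tiny_fit["results"].draws["omega"]
        observed_cols = ds.species_totals().any(axis=0)
        assert (omega[:, :, observed_cols] == 1).all()

    def test_binary_and_probability_draws_in_range(self, tiny_fit):
        res = tiny_fit["results"]
        assert set(np.unique(res.draws["theta"])) <= {0, 1}
        assert set(np.unique(res.draws["omega"])) <= {0, 1}
        assert ((res.draws["Omega"] >= 0) & (res.draws["Omega"] <= 1)).all()
        assert (res.draws["lam"] > 0).all()

    def test_supercommunity_must_cover_observed(self, small_dataset):
        ds = small_dataset.copy()
        ds.n_observed = 5  # claim more observed species than columns
        with pytest.raises(ValueError):
            ZIPNMixtureModel(ds)

    def test_all_zero_dataset_warns_and_returns_prior_dominated(self):
        ds = InteractionDataset(
            counts=np.zeros((2, 3), dtype=int),
            plant_species_of=np.array([0, 1]),
            plant_labels=["P0", "P1"], animal_labels=["a0", "a1", "a2"],
            individual_labels=["i0", "i1"], n_observed=3,
        )
        with pytest.warns(UserWarning, match="prior-dominated"):
            res = ZIPNMixtureModel(ds).fit(n_chains=2, n_iter=500, thin=5, seed=0)
        assert res.draws["N"].size > 0

    def test_prior_only_recovers_prior_moments(self, small_dataset):
        ds = augment_dataset(small_dataset, 10)
        res = ZIPNMixtureModel(ds).fit(n_chains=4, n_iter=4000, thin=4,
                                       burn_in=1000, seed=8, prior_only=True)
        Om = res.stacked("Omega")
        assert Om.mean() == pytest.approx(0.5, abs=0.05)       # U(0,1) mean
        assert Om.var() == pytest.approx(1 / 12, abs=0.02)     # U(0,1) variance
        # half-Cauchy(0, 10) has median 10; heavy tails, so compare medians
        assert 5 < np.median(res.stacked("sigma_alpha")) < 20
        assert 5 < np.median(res.stacked("sigma_beta")) < 20
        # omega marginalises to Bernoulli(Omega) with E = 1/2
        assert res.stacked("N").mean() / ds.supercommunity_size == pytest.approx(0.5, abs=0.06)

    def test_extension_appends_draws(self, tiny_fit):
        model = tiny_fit["model"]
        base = tiny_fit["results"]
        ext = model.continue_fit(base, 1000)
        assert ext.draws["N"].shape[1] > base.draws["N"].shape[1]
        assert ext.extended == 1
        # original draws are preserved verbatim at the front
        assert np.array_equal(ext.draws["N"][:, : base.draws["N"].shape[1]],
                              base.draws["N"])


class TestConvergence:
    def test_converged_run_reports_rhat_below_threshold(self, hiha_recovery):
        res = hiha_recovery["results"]
        assert res.max_rhat < res.config.rhat_threshold
        assert res.converged
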