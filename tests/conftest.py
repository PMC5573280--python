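"""Shared fixtures.

The expensive MCMC fits are session-scoped so that the recovery experiment
is run once and inspected by several tests.
"""

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coextnet.data import from_long_frame
from coextnet.evaluation import abundance_recovery, interaction_roc
from coextnet.model import ZIPNMixtureModel
from coextnet.simulate import preset_config, simulate_scenario

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def long_df() -> pd.DataFrame:
    """Three observation records over two plant individuals."""
    return pd.DataFrame({
        "individual": ["i1", "i1", "i2"],
        "plant_species": ["PkA", "PkA", "PkB"],
        "animal_species": ["aj1", "aj2", "aj1"],
        "count": [2, 0, 1],
    })


@pytest.fixture
def small_dataset(long_df):
    return from_long_frame(long_df)


@pytest.fixture(scope="session")
def tiny_fit():
    """A small but real fit used for structural checks on the posterior."""
    cfg = preset_config("HIHA", samples_per_plant=10, seed=2,
                        n_plants=3, n_animals=8)
    truth, _, observed, kept = simulate_scenario(cfg, m_augment=5)
    model = ZIPNMixtureModel(observed)
    results = model.fit(n_chains=2, n_iter=2000, thin=10, seed=4)
    return {"truth": truth, "observed": observed, "kept": kept,
            "model": model, "results": results}


@pytest.fixture(scope="session")
def hiha_recovery():
    """Parameter-recovery experiment on a reduced high/high scenario.

    5 plant species, 30 animal species, 20 sampled individuals per plant,
    supercommunity of 50, four chains of 20,000 iterations.
    """
    cfg = preset_config("HIHA", samples_per_plant=20, seed=11,
                        n_plants=5, n_animals=30)
    truth, _, observed, kept = simulate_scenario(cfg, m_augment=20)
    results = ZIPNMixtureModel(observed).fit(
        n_chains=4, n_iter=20_000, thin=100, seed=3)
    pm_theta = results.posterior_mean_theta()[:, : kept.size]
    _, auc = interaction_roc(truth.theta[:, kept], pm_theta)
    has_partner = truth.theta[:, kept].sum(axis=0) > 0
    table, agg = abundance_recovery(truth.lam[kept], results,
                                    score_mask=has_partner)
    return {
        "truth": truth, "observed": observed, "kept": kept,
        "results": results, "auc": auc,
        "recovery_table": table, "recovery_agg": agg,
    }
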