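import numpy as np
import pytest

from dcrws import MCMCConfig, SimScenario, fit_dcrws, simulate_track


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic deployment used across the suite."""
    return SimScenario(seed=42)


@pytest.fixture(scope="session")
def sim_track(scenario):
    latent, track = simulate_track(scenario)
    return latent, track


@pytest.fixture(scope="session")
def short_mcmc():
    """Desk-scale chain settings that still satisfy the retention invariant."""
    return MCMCConfig(n_chains=2, n_iter=8_000, n_burnin=3_000, thin=5, seed=42)


@pytest.fixture(scope="session")
def sim_fit(scenario, sim_track, short_mcmc):
    """One shared fit of the default synthetic track (used by many tests)."""
    latent, track = sim_track
    res = fit_dcrws(track, step_hours=scenario.step_hours, mcmc=short_mcmc)
    return latent, track, res


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
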