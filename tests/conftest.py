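import pytest

from glmmscore import DGPConfig, MCMCConfig, fit_mcmc, generate_nb_longitudinal
from glmmscore.pipeline import simulation_model_spec


@pytest.fixture(scope="session")
def tiny_mcmc():
    """Very small sampler budget for structural/contract tests."""
    return MCMCConfig(chains=2, iters=600, thin=3)


@pytest.fixture(scope="session")
def desk_mcmc():
    """Reduced but statistically usable budget."""
    return MCMCConfig(chains=2, iters=2400, thin=3)


@pytest.fixture(scope="session")
def small_nb_data():
    return generate_nb_longitudinal(DGPConfig(k=5.0, n_per_group=10, seed=11))


@pytest.fixture(scope="session")
def toy_poisson_data():
    """6 subjects x 3 visits, Poisson counts."""
    cfg = DGPConfig(family="poisson", n_per_group=3, times=(0.0, 1.0, 2.0),
                    alpha=2.0, sigma_a=0.4, seed=5)
    return generate_nb_longitudinal(cfg)


@pytest.fixture(scope="session")
def small_nb_fit(small_nb_data, desk_mcmc):
    return fit_mcmc(simulation_model_spec("nb"), small_nb_data,
                    mcmc=desk_mcmc, seed=21)
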