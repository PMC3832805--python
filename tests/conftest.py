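import numpy as np
import pytest

from pitnet import (
    McmcConfig,
    ParadigmConfig,
    PriorSpec,
    default_network_spec,
    fit_posterior,
    generate_paradigm,
)


@pytest.fixture(scope="session")
def spec():
    return default_network_spec()


@pytest.fixture(scope="session")
def tiny_paradigm():
    """Scaled-down paradigm for fast unit-level fits."""
    return ParadigmConfig(
        n_pavlovian_per_cs=40,
        n_instrumental_per_lever=150,
        n_blank=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_mcmc():
    return McmcConfig(n_iterations=1200, n_burn_in=400, thinning=2, seed=5)


@pytest.fixture(scope="session")
def tiny_fit(spec, tiny_paradigm, tiny_mcmc):
    """A small but real posterior fit shared across unit tests."""
    trials = generate_paradigm(tiny_paradigm, spec)
    return fit_posterior(trials, spec, PriorSpec(), tiny_mcmc)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
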