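import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import compositebias as cb

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def counterexample():
    """Parallel-measures model whose composite plim of path 1 is exactly 0."""
    return cb.make_counterexample(gamma1=0.25)


@pytest.fixture(scope="session")
def counterexample_cov(counterexample):
    return cb.implied_indicator_cov(counterexample)


@pytest.fixture(scope="session")
def null_model():
    """Model with a truly zero first path and correlated exogenous latents."""
    return cb.make_null_model()


@pytest.fixture(scope="session")
def mediation_model():
    return cb.make_mediation_model()


@pytest.fixture(scope="session")
def counterexample_ewc(counterexample, counterexample_cov):
    return cb.weights_equal(counterexample_cov, counterexample.blocks,
                            latent_order=counterexample.latent_names)


def edges_of(model):
    return [(s, d) for s, d, _ in model.structural]


@pytest.fixture(scope="session")
def random_model_cov():
    model = cb.make_random_model(k_exo=2, k_endo=2, indicators_per_block=3,
                                 seed=42)
    return model, cb.implied_indicator_cov(model)


def rng(seed=0):
    return np.random.default_rng(seed)
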