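import numpy as np
import pytest

from latertwin.simulate import (
    DopplerSimConfig,
    TwinSimConfig,
    simulate_doppler_session,
    simulate_twin_phenotypes,
)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free Doppler session with a known 2.0 pp lateralised response."""
    cfg = DopplerSimConfig(
        n_trials=20, response_delta=2.0, noise_sd=0.0, drift_sd=0.0, seed=101
    )
    return simulate_doppler_session(cfg)


@pytest.fixture(scope="session")
def noisy_session():
    """Realistic session: noise, drift, injected rejections."""
    cfg = DopplerSimConfig(
        n_trials=30,
        response_delta=2.0,
        dropout_prob=0.1,
        artifact_prob=0.1,
        behaviour_invalid_prob=0.05,
        seed=202,
    )
    return simulate_doppler_session(cfg)


@pytest.fixture(scope="session")
def ae_cohort():
    """Twin cohort simulated under a2=0.5, e2=0.5 (1000/1000 pairs)."""
    cfg = TwinSimConfig(n_mz=1000, n_dz=1000, a2=0.5, c2=0.0, e2=0.5, seed=11)
    return simulate_twin_phenotypes(cfg)


def make_cohort(n_mz, n_dz, a2, c2, seed, marginal="normal"):
    cfg = TwinSimConfig(
        n_mz=n_mz, n_dz=n_dz, a2=a2, c2=c2, e2=1 - a2 - c2,
        marginal=marginal, seed=seed,
    )
    return simulate_twin_phenotypes(cfg)
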