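import numpy as np
import pytest

from hpr import (
    FamilySpec,
    ObservedData,
    SamplerConfig,
    ScenarioSpec,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231214)


@pytest.fixture(scope="session")
def short_sampler():
    """Two short chains, enough for integration smoke tests."""
    return SamplerConfig(chains=2, warmup=200, sampling=200, seed=7)


@pytest.fixture(scope="session")
def tiny_sampler():
    """One very short chain for plumbing tests."""
    return SamplerConfig(chains=1, warmup=100, sampling=100, seed=3)


@pytest.fixture(scope="session")
def bigstep_small():
    """A small bigstep dataset (n=40) for fast model fits."""
    return simulate_dataset(ScenarioSpec("bigstep", n=40), seed=5)


@pytest.fixture
def gaussian_data(rng):
    x = np.linspace(0.0, 10.0, 12)
    y = np.where(x > 5, 3.0, 0.0) + 0.3 * np.asarray(
        np.random.default_rng(1).standard_normal(12)
    )
    return ObservedData(y=y, x=x, family=FamilySpec("gaussian"))
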