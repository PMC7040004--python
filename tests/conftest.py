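import numpy as np
import pytest

from halodyn import DynamicsModel, InstrumentConfig, simulate_elastic_bundle


@pytest.fixture
def instrument():
    return InstrumentConfig()


@pytest.fixture
def make_bundle(instrument):
    """Factory for single- or multi-population elastic bundles."""

    def _make(populations, seed=0, noise=False, **model_kwargs):
        model = DynamicsModel(populations=populations, **model_kwargs)
        return simulate_elastic_bundle(model, instrument, seed=seed, noise=noise)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
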