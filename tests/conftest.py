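import numpy as np
import pytest

from oncoqc.simulate import GeneratorConfig, generate_study


def small_config(**overrides) -> GeneratorConfig:
    """A reduced study: same geometry, fewer variants — fast for unit tests."""
    defaults = dict(
        n_kp=400,
        n_kn=30_000,
        n_germline=400,
        n_spikein=60,
        depth=800.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_study(small_config(), seed=42)


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size study bundle at the reference conditions."""
    return generate_study(seed=2021)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
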