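import numpy as np
import pytest

from chromodor import GeneratorConfig, generate_dataset, null_dataset

ODORS_4 = ("burnt", "candy", "fish", "flower")


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        groups={"alpha": 6, "beta": 6}, odors=ODORS_4,
        kappa=0.2, rho=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_null_dataset(small_config):
    return null_dataset(small_config)


@pytest.fixture(scope="session")
def group20_dataset():
    """One 20-participant group over the full 14 odors, clear associations."""
    cfg = GeneratorConfig(groups={"solo": 20}, kappa=0.1, rho=0.0, seed=3)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def group20_null():
    cfg = GeneratorConfig(groups={"solo": 20}, seed=5)
    return null_dataset(cfg)
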