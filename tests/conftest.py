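import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ieaco
from ieaco.io import builtin_model_names, load_builtin_model

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def models():
    """The eight packaged two-locus epistasis models, keyed by name."""
    return {name: load_builtin_model(name) for name in builtin_model_names()}


@pytest.fixture(scope="session")
def model1(models):
    return models["model1"]


@pytest.fixture(scope="session")
def model3(models):
    return models["model3"]


@pytest.fixture(scope="session")
def small_dataset(model1):
    """Model 1 dataset, 20 SNPs, 200 cases / 200 controls, pair at (3, 15)."""
    return ieaco.simulate_dataset(
        model1, n_snps=20, n_cases=200, n_controls=200,
        pair_positions=(3, 15), seed=11,
    )


@pytest.fixture()
def uniform_model():
    """Constant-penetrance model: the embedded pair carries no signal."""
    return ieaco.PenetranceModel("null", 0.3, 0.3, np.full((3, 3), 0.1))
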