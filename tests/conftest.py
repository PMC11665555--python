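import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import resistomics as rx
from resistomics.simulate import SimulationSpec, gen_bundle

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A fast, fully coupled simulation for integration-style tests."""
    return SimulationSpec(
        seed=11, n_genes=1500, n_deg=150, n_tfs=20,
        regulon_size_range=(30, 80), n_pathways=8, n_metabolites=60,
        n_perturbed_metabolites=6, n_subjects=200,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return gen_bundle(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture()
def config() -> rx.AnalysisConfig:
    return rx.AnalysisConfig(seed=11, permutations=500)
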