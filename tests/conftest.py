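import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pyropk.cohort import CohortDesign, apply_data_rules, generate_cohort
from pyropk.datatypes import final_model
from pyropk.foce import fit_foce, pack_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def final_spec():
    return final_model()


@pytest.fixture(scope="session")
def sparse_subjects(final_spec):
    """Default sparse study cohort (50 subjects, 158 samples) after the
    BLQ/data-handling rules."""
    sim = generate_cohort(CohortDesign(), final_spec, seed=42)
    clean, _ = apply_data_rules(sim.subjects)
    return clean


@pytest.fixture(scope="session")
def sparse_packed(sparse_subjects):
    return pack_dataset(sparse_subjects)


@pytest.fixture(scope="session")
def sparse_fit(sparse_packed, final_spec):
    """Final-model FOCE-I fit of the sparse cohort, shared by diagnostics
    tests."""
    return fit_foce(sparse_packed, final_spec, maxiter=400)


@pytest.fixture
def rng():
    return np.random.default_rng(20240920)
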