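import numpy as np
import pytest
from hypothesis import settings

from nspec import (
    SimulationConfig,
    SpectralDataset,
    StudyConfig,
    run_study,
    simulate_dataset,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_dataset(matrix, wavelengths=None, leaf_n=None, domain_tag="reflectance"):
    """Small hand-built dataset helper used across test modules."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    if wavelengths is None:
        wavelengths = 400.0 + np.arange(p)
    if leaf_n is None:
        leaf_n = np.linspace(2.0, 5.0, n)
    return SpectralDataset(
        wavelengths=wavelengths,
        reflectance=matrix,
        leaf_n=np.asarray(leaf_n, dtype=float),
        domain_tag=domain_tag,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Seeded synthetic dataset at the default study conditions (n=315)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def study_report():
    """One full seeded study run shared by the end-to-end checks."""
    return run_study(StudyConfig(seed=7, simulation=SimulationConfig(seed=7)))
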