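import numpy as np
import pytest

from gaitrec.synthetic import CohortSpec, default_archetypes, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Default study-scale cohort: 31 patients, 3 archetypes, Table-2 missingness."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def complete_cohort():
    """Fully observed default cohort (no missingness applied)."""
    return generate_cohort(CohortSpec(missingness_profile=None, seed=0))


@pytest.fixture(scope="session")
def two_archetype_clean():
    """Small zero-noise cohort with two well-separated archetypes."""
    spec = CohortSpec(
        n_patients=12,
        archetypes=default_archetypes(2),
        noise_sd=0.0,
        missingness_profile=None,
        seed=1,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def six_archetype_cohort():
    """48 patients, six well-separated archetypes, modest noise, complete."""
    spec = CohortSpec(
        n_patients=48,
        archetypes=default_archetypes(6),
        noise_sd=1.0,
        missingness_profile=None,
        seed=2,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
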