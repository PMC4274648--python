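import pytest

from dtdct import reconstruct_fixture_cohort, sample_cohort, study_params


@pytest.fixture(scope="session")
def table4_cohort():
    return reconstruct_fixture_cohort("table4", seed=1)


@pytest.fixture(scope="session")
def section3_cohort():
    return reconstruct_fixture_cohort("section3", seed=1)


@pytest.fixture(scope="session")
def sampled_cohort():
    """A moderate random cohort with the study's class structure."""
    params = study_params()
    params.class_sizes = {
        "normal": 120,
        "hashimoto": 13,
        "non_hashimoto_lt": 26,
        "diffuse_hyperplasia": 1,
    }
    return sample_cohort(params, seed=42)
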