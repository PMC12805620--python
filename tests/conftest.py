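import pytest

from gpstils import CohortConfig, PipelineConfig, generate_cohort, score_patches


@pytest.fixture(scope="session")
def small_cohort():
    """Eight patients with nuclei coordinates; cheap enough for oracles."""
    return generate_cohort(CohortConfig(n_patients=8, seed=7, patches_per_slide_mean=10))


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    return score_patches(small_cohort.nuclei, small_cohort.patches)


@pytest.fixture()
def config():
    return PipelineConfig()
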