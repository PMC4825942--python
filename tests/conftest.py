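import numpy as np
import pytest

from methylmark import synthetic as syn


@pytest.fixture(scope="session")
def study_config():
    return syn.study_cohort_config(seed=0)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return syn.generate_cohort(study_config)


@pytest.fixture(scope="session")
def noise_free_assay():
    return syn.AssaySimConfig(
        qmsp_noise_sd=0.0,
        expression_noise_sd=0.0,
        array_beta_noise_sd=0.0,
        conversion_efficiency=1.0,
        sequencing_error_rate=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def study_reference():
    return syn.make_reference(syn.STUDY_CPG_TSS_OFFSETS, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
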