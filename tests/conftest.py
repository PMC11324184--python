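import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# statsmodels emits convergence chatter on boundary variance estimates;
# skbio warns about small negative PCoA eigenvalues — both are expected here
warnings.filterwarnings("ignore", category=RuntimeWarning, module="skbio")
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture(scope="session")
def microcosm_default():
    """Default pot-experiment dataset, seed 1."""
    from befmf import generate_microcosm

    return generate_microcosm(seed=1)


@pytest.fixture(scope="session")
def survey_default():
    """Default survey dataset, seed 1."""
    from befmf import generate_survey

    return generate_survey(seed=1)
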