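import pytest
from hypothesis import HealthCheck, settings

from pfcea import Cohort, reference_base_cases

settings.register_profile(
    "deterministic",
    deadline=None,
    max_examples=60,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_cases():
    """The three reference cohorts, keyed by cohort enum."""
    return {c.cohort: c for c in reference_base_cases()}


@pytest.fixture(scope="session")
def brca(ref_cases):
    return ref_cases[Cohort.BRCA_VARIANT]


@pytest.fixture(scope="session")
def hrd(ref_cases):
    return ref_cases[Cohort.HRD_BRCA_WT]


@pytest.fixture(scope="session")
def hrp(ref_cases):
    return ref_cases[Cohort.HR_PROFICIENT]
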