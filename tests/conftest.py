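import pytest
from hypothesis import HealthCheck, settings

from snvcalib import (
    SimParams,
    default_scheme,
    load_reference_crosstab,
    simulate_cohort,
    synthetic_study_records,
)

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SET_IDS = ("set1", "set2", "set3", "set4")


@pytest.fixture(scope="session")
def reference_tabs():
    return {sid: load_reference_crosstab(sid) for sid in SET_IDS}


@pytest.fixture(scope="session")
def study_records():
    return {sid: synthetic_study_records(sid) for sid in SET_IDS}


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimParams(n_variants=3000), seed=20240)


@pytest.fixture(scope="session")
def samtools_scheme():
    return default_scheme("samtools")


@pytest.fixture(scope="session")
def gatk_scheme():
    return default_scheme("gatk")
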