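import warnings

import pytest
from hypothesis import HealthCheck, settings

import xenodissect as xd

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="dropping collinear design column")


@pytest.fixture(scope="session")
def partition_fixture():
    return xd.build_cohort_fixture("partition_demo")


@pytest.fixture(scope="session")
def de_fixture():
    return xd.build_cohort_fixture("de_demo")


@pytest.fixture(scope="session")
def triad_fixture():
    return xd.build_cohort_fixture("triad_demo")


@pytest.fixture(scope="session")
def signature_fixture():
    return xd.build_cohort_fixture("signature_demo")


@pytest.fixture(scope="session")
def tiny_refs():
    return xd.generate_reference(
        n_genes=10, n_orthologs=4, divergence=0.10, transcript_length=120, seed=5
    )
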