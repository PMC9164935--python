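import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dilicat.datasets import sportif2_cases, sportif3_subset1_cases
from dilicat.phenotype import build_phenotype, refine_phenotype


@pytest.fixture(scope="session")
def seed_cases():
    """The five drug-arm cases that seed the preliminary phenotype."""
    return sportif2_cases()


@pytest.fixture(scope="session")
def validation_cases():
    """The eight validation cases (five drug, three comparator)."""
    return sportif3_subset1_cases()


@pytest.fixture(scope="session")
def phenotype_v1(seed_cases):
    """Preliminary phenotype, inclusive quantile dialect."""
    return build_phenotype(seed_cases, dialect="inclusive")


@pytest.fixture(scope="session")
def phenotype_v2(seed_cases, validation_cases):
    """Refined ten-case phenotype, exclusive quantile dialect."""
    new = [c for c in validation_cases if c.arm == "drug"]
    return refine_phenotype(seed_cases, new, dialect="exclusive")
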