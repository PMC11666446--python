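import pytest

from ebmscale import CohortSpec, apply_inclusion_filters, generate_cohort

SEED = 0


@pytest.fixture(scope="session")
def small_healthy():
    """A small healthy cohort for fast unit tests."""
    return generate_cohort(CohortSpec.healthy(n=800), seed=SEED)


@pytest.fixture(scope="session")
def default_healthy():
    """The full-size healthy cohort after inclusion filtering."""
    cohort = generate_cohort(CohortSpec.healthy(n=5618), seed=SEED)
    filtered, _ = apply_inclusion_filters(cohort)
    return filtered
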