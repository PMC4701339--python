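import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fallgrf",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fallgrf")


@pytest.fixture(scope="session")
def calibrated_cohort_features():
    """Feature table of a default-calibrated cohort, n=100 per group.

    Session-scoped: this is the most expensive fixture (200 subjects x 8
    channels of sample entropy) and several checks share it.
    """
    from fallgrf.features import extract_feature_table
    from fallgrf.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_fallers=100, n_nonfallers=100, seed=11)
    return extract_feature_table(generate_cohort(spec))


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny but complete cohort (4 + 4 subjects, short series)."""
    from fallgrf.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_fallers=4, n_nonfallers=4, seed=5, series_length=300)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
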