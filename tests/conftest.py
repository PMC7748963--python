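import pytest

from stopsense.synth import CohortConfig, make_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-participant, 4-day cohort shared by read-only tests."""
    return make_cohort(CohortConfig(n_participants=3, days=4, seed=1))
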