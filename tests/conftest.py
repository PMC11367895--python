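import hypothesis
import pytest

from aecopd.agreement import ContingencyTable2x2
from aecopd.simulate import SyntheticCohortConfig, generate_cohort

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def copd_table():
    """Published 2x2 for the full COPD cohort with EHR review (n=222)."""
    return ContingencyTable2x2(a=137, b=19, c=28, d=38)


@pytest.fixture(scope="session")
def bronchoscopy_table():
    """Published 2x2 for the COPD bronchoscopy subset (n=41)."""
    return ContingencyTable2x2(a=14, b=6, c=9, d=12)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticCohortConfig(n_participants=300, seed=11))
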