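import hypothesis
import pytest

from cemquant.cohort import (
    DEFAULT_PARAMS,
    SimulationParams,
    build_exclusion_fixture,
    build_paper_fixture,
    simulate_cohort,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100,
    suppress_health_check=[hypothesis.HealthCheck.too_slow],
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def exclusion_fixture():
    return build_exclusion_fixture()


@pytest.fixture(scope="session")
def simulated_cohort():
    """A mid-size calibrated cohort shared by statistical tests."""
    params = SimulationParams(classes=DEFAULT_PARAMS.classes,
                              n_lesions=600, seed=11)
    return simulate_cohort(params)
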