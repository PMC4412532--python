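import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from sportsrisk.calibration import derive_bins, exact_score_distribution
from sportsrisk.panel import load_fixture_panel


@pytest.fixture(scope="session")
def fixture_panel():
    return load_fixture_panel()


@pytest.fixture(scope="session")
def combined_subset(fixture_panel):
    return fixture_panel.combined_score_subset()


@pytest.fixture(scope="session")
def exact_dist(combined_subset):
    return exact_score_distribution(combined_subset)


@pytest.fixture(scope="session")
def quintile_scheme(exact_dist):
    return derive_bins(exact_dist)
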