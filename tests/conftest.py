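import itertools

import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from penrisk import (
    GradingSystem,
    HistopathProfile,
    expand_fixture_to_records,
    reference_fixture,
)


@pytest.fixture(scope="session")
def fixture():
    return reference_fixture()


@pytest.fixture(scope="session")
def expanded_records(fixture):
    """Pseudo-cohort of 306 records reproducing the proposed contingency."""
    return expand_fixture_to_records(fixture, seed=0, system=GradingSystem.PROPOSED)


@pytest.fixture(scope="session")
def all_profiles():
    """All 48 feature combinations (4 WPOI x 3 LHR x 2 LVI x 2 PNI)."""
    return [
        HistopathProfile(w, l, lv, pn)
        for w, l, lv, pn in itertools.product(range(1, 5), range(1, 4), (False, True), (False, True))
    ]
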