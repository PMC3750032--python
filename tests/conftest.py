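import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import falut


@pytest.fixture(scope="session")
def paper_scheme_table():
    """Synthetic normative table at the published 12-direction parameters."""
    return falut.generate_measurements(list(falut.DEFAULT_SCHEME_12MPG), seed=1)


@pytest.fixture(scope="session")
def fits_12(paper_scheme_table):
    return falut.fit_all_groups(paper_scheme_table, mpg_scheme=12)


@pytest.fixture(scope="session")
def lut12():
    return falut.builtin_lut(12)


@pytest.fixture(scope="session")
def lut30():
    return falut.builtin_lut(30)
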