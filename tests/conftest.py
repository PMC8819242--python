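import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_table():
    from t2risk import load_table1_fixture

    return load_table1_fixture()


@pytest.fixture(scope="session")
def printed_reductions():
    from t2risk import load_table1_reductions

    return load_table1_reductions()
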