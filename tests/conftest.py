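import pytest
from hypothesis import HealthCheck, settings

from hemiopsin import evodist, fixtures, tuning

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def jtt():
    return evodist.jtt_model()


@pytest.fixture(scope="session")
def gamma1():
    return evodist.discrete_gamma(1.0, 4)


@pytest.fixture(scope="session")
def aphid_fixture():
    return fixtures.paralog_state_fixture("aphid")


@pytest.fixture(scope="session")
def planthopper_fixture():
    return fixtures.paralog_state_fixture("planthopper")


def _survey(fx, lineage):
    return tuning.survey_clades(
        fx["alignment"], fx["sitemaps"], fx["uv_anc"], fx["uv_der"],
        fx["outgroups"], lineage=lineage,
    )


@pytest.fixture(scope="session")
def aphid_survey(aphid_fixture):
    return _survey(aphid_fixture, "aphid")


@pytest.fixture(scope="session")
def planthopper_survey(planthopper_fixture):
    return _survey(planthopper_fixture, "planthopper")
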