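import pytest

from ebis.fixtures import make_case_like_fixture, make_point_mass_fixture


@pytest.fixture(scope="session")
def point_mass_manifest():
    return make_point_mass_fixture()


@pytest.fixture(scope="session")
def point_mass_spec(point_mass_manifest):
    return point_mass_manifest.spec


@pytest.fixture(scope="session")
def case_manifest():
    return make_case_like_fixture()


@pytest.fixture(scope="session")
def case_spec(case_manifest):
    return case_manifest.spec
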