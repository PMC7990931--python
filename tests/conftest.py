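import pytest

from orcascape import load_fixture, load_fixture_expected, CalibrationModel, SuessModel


@pytest.fixture(scope="session")
def fixture_records():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_expected():
    return {e["specimen_id"]: e for e in load_fixture_expected()}


@pytest.fixture(scope="session")
def calib():
    return CalibrationModel()


@pytest.fixture(scope="session")
def suess_model():
    return SuessModel()
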