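import pytest

from chd4var import load_chd4_architecture, load_study_fixture


@pytest.fixture(scope="session")
def study_variants():
    """The packaged 36-variant CHD4 study fixture."""
    return load_study_fixture()


@pytest.fixture(scope="session")
def missense(study_variants):
    return [v for v in study_variants if v.is_missense]


@pytest.fixture(scope="session")
def arch():
    return load_chd4_architecture()
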