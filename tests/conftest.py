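import pytest
from hypothesis import settings

from mr2s.harmonize import harmonize_fixture
from mr2s.summary_io import load_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture():
    """The packaged 70-SNP BMI/MS instrument table."""
    return load_fixture()


@pytest.fixture(scope="session")
def instruments(fixture):
    """All 70 harmonized instruments with AF-band flags attached."""
    return harmonize_fixture(fixture)
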