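import pytest

from asc_time.io import load_table2_fixture


@pytest.fixture(scope="session")
def cohort():
    """The bundled 46-patient real-world ICI cohort."""
    return load_table2_fixture()


@pytest.fixture
def rng_seed():
    return 20220812
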