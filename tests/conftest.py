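import pytest

from imsp.encoding import load_pcp_table
from imsp.synthetic_data import make_benchmark_suite


@pytest.fixture(scope="session")
def pcp_table():
    return load_pcp_table()


@pytest.fixture(scope="session")
def suite():
    """The fixed benchmark fixture suite at seed 0 (shared, read-only)."""
    return make_benchmark_suite(0)
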