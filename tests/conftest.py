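import pytest

from comolead.adme import literature_profiles
from comolead.docking import packaged_table


@pytest.fixture(scope="session")
def table():
    """The packaged 20-row docking-score table."""
    return packaged_table()


@pytest.fixture(scope="session")
def profiles():
    """Literature ADME profiles of the four designed inhibitors."""
    return literature_profiles()
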