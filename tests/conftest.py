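import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mrtkit import nuclides  # noqa: E402


@pytest.fixture(scope="session")
def lu177():
    return nuclides.load_nuclide("Lu-177")


@pytest.fixture(scope="session")
def in111():
    return nuclides.load_nuclide("In-111")


@pytest.fixture(scope="session")
def csda_table():
    from mrtkit.celldose import _csda_table
    return _csda_table()
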