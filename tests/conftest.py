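import datetime

import pytest

from cdspack import default_engine
from cdspack.hypertension import PACK_DIR
from cdspack.kb import load_pack

NOW = datetime.date(2024, 3, 1)


@pytest.fixture(scope="session")
def pack():
    return load_pack(PACK_DIR)


@pytest.fixture(scope="session")
def registry(pack):
    return pack.registry


@pytest.fixture(scope="session")
def engine():
    return default_engine(now=NOW)


@pytest.fixture()
def now():
    return NOW
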