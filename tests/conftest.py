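from datetime import datetime

import pytest
from hypothesis import settings

from icualarms import AnnotationConfig, load_mappings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

T0 = datetime(2024, 1, 1, 12, 0, 7)


@pytest.fixture(scope="session")
def mapping():
    return load_mappings()


@pytest.fixture(scope="session")
def config():
    return AnnotationConfig()
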