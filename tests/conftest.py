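import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from beetracker import GeoPoint


@pytest.fixture
def hainich() -> GeoPoint:
    """Representative mid-latitude beech-forest study point."""
    return GeoPoint(51.08, 10.43)
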