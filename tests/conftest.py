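import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from urolab import grading


@pytest.fixture(scope="session")
def table():
    """Default eight-level grading table from the published regression."""
    return grading.build_grading_table()


@pytest.fixture()
def solid_image():
    """Noiseless solid-color cuvette stand-in (amber-ish tone)."""
    return np.full((120, 160, 3), (200, 180, 60), dtype=np.uint8)
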