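import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_mask(rng: np.random.Generator, h: int, w: int, p: float = 0.4) -> np.ndarray:
    return rng.random((h, w)) < p
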