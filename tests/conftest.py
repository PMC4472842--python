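import numpy as np
import pytest

from biofilmsim.lattice import BiofilmState, GridConfig


def random_state(seed: int, width: int = 12, depth: int = 10, density: float = 0.3) -> BiofilmState:
    """Random occupancy grid for oracle tests (connectivity not required)."""
    rng = np.random.default_rng(seed)
    occ = (rng.random((depth, width)) < density).astype(np.uint8)
    return BiofilmState(GridConfig(width, depth), occ)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
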