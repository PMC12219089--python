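import numpy as np
import pytest

# 5x5 distance-like matrix used throughout: five zeros on the diagonal,
# two merges at value 1, one at 2, full connection at 3, and two corner
# minima born at 1 that survive until 3.  Its 0-dim sublevel persistence
# is known in closed form (verified against the flood-fill oracle).
FIG2 = np.array(
    [
        [0, 1, 3, 3, 1],
        [1, 0, 2, 3, 3],
        [3, 2, 0, 1, 3],
        [3, 3, 1, 0, 3],
        [1, 3, 3, 3, 0],
    ],
    dtype=float,
)

FIG2_FINITE_PAIRS = [(0.0, 1.0), (0.0, 1.0), (0.0, 2.0), (0.0, 3.0), (1.0, 3.0), (1.0, 3.0)]
FIG2_ESSENTIAL = [0.0]
FIG2_BETTI = {-1: 0, 0: 5, 1: 5, 2: 4, 3: 1}


@pytest.fixture
def fig2_matrix():
    return FIG2.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
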