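import numpy as np
import pytest

# Table of leaf-shift measurements (mm) per gantry angle: nominal picket
# positions at 0, +-4, +-8, +-12 cm in the cross-plane direction.
PICKET_NOMINALS_CM = [-12.0, -8.0, -4.0, 0.0, 4.0, 8.0, 12.0]
LEAF_SHIFTS_MM = {
    0: [0.3, 0.0, -0.5, 0.0, 0.3, -0.1, 0.2],
    90: [0.2, 0.1, -0.4, 0.0, 0.3, 0.0, 0.5],
    180: [0.1, 0.1, -0.5, 0.0, 0.3, -0.1, 0.3],
    270: [0.3, 0.1, -0.4, 0.0, 0.2, -0.2, 0.1],
}
LEAF_STATS_MM = {0: (0.03, 0.28), 90: (0.10, 0.28), 180: (0.03, 0.28), 270: (0.01, 0.24)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
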