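import numpy as np
import pytest

from trajlca.panel import ResponsePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_wave_toy_panel():
    """Four response patterns: (0,0) x40, (1,1) x40, (1,0) x10, (0,1) x10."""
    values = np.vstack(
        [
            np.tile([0.0, 0.0], (40, 1)),
            np.tile([1.0, 1.0], (40, 1)),
            np.tile([1.0, 0.0], (10, 1)),
            np.tile([0.0, 1.0], (10, 1)),
        ]
    )
    return ResponsePanel(values, np.arange(100), "toy")


@pytest.fixture
def missing_pattern_panel():
    """Five children with hand-set missingness over (3 soiling, 4 constipation) waves."""
    nan = np.nan
    soil = ResponsePanel(
        np.array(
            [
                [0, 1, 0],
                [nan, nan, 1],
                [0, 0, 0],
                [1, nan, nan],
                [nan, nan, nan],
            ],
            dtype=float,
        ),
        np.arange(5),
        "soiling",
    )
    con = ResponsePanel(
        np.array(
            [
                [0, 0, 0, 0],
                [1, 1, 1, 1],
                [nan, 0, 0, 1],
                [0, 1, nan, nan],
                [0, 0, 0, nan],
            ],
            dtype=float,
        ),
        np.arange(5),
        "constipation",
    )
    return soil, con
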