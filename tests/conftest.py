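import warnings

import numpy as np
import pytest

from codefrp.containers import GazeStream
from codefrp.synthetic import GazeNoiseSpec, generate_layout

# participant-dropped warnings are expected in tiny designs
warnings.filterwarnings(
    "ignore", message="participant .* dropped", category=UserWarning
)


@pytest.fixture
def layout10():
    """Ten all-informative lines, AOI on one of them."""
    return generate_layout(10, seed=1)


@pytest.fixture
def layout_braces():
    """Eight lines with two uninformative (brace-only) ones."""
    pattern = [True, True, False, True, True, True, False, True]
    return generate_layout(8, informative_pattern=pattern, seed=2)


@pytest.fixture
def quiet_noise():
    return GazeNoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0)


def make_stream(x, y, valid=None, rate_hz=1200.0, trial_id="t"):
    x = np.asarray(x, float)
    n = len(x)
    if valid is None:
        valid = np.ones(n, bool)
    return GazeStream(
        trial_id=trial_id,
        t_ms=np.arange(n) * 1000.0 / rate_hz,
        x_px=x,
        y_px=np.asarray(y, float),
        valid=np.asarray(valid, bool),
        rate_hz=rate_hz,
    )
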