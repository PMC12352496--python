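import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dsgckit.traces import ResponseWindows

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

EIGHT_DIRECTIONS = np.arange(8) * 45.0


@pytest.fixture
def directions():
    return EIGHT_DIRECTIONS.copy()


@pytest.fixture
def windows():
    return ResponseWindows()


@pytest.fixture
def fast_windows():
    """Short windows for sweeps generated at reduced duration."""
    return ResponseWindows(on_start=0.3, off_start=1.1, width=0.6, baseline_width=0.2)
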