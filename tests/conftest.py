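import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from xiclink.calibration import make_calibration
from xiclink.model import run_from_points


@pytest.fixture
def make_run():
    """Build a Run from (mz, rt, intensity) triples."""
    return run_from_points


@pytest.fixture
def injected_calib():
    """A Calibration with chosen values, bypassing estimation."""

    def _make(baseline=10.0, resolution_mz=0.01, sampling_rate_rt=1.0, mode="centroid"):
        return make_calibration(baseline, resolution_mz, sampling_rate_rt, mode)

    return _make
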