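import numpy as np
import pytest

from fictivemotor.io import ROI_ORDER_18, ROI_ORDER_9, RoiTraceSet
from fictivemotor.preprocess import NormTraceSet
from fictivemotor.synthetic import SimConfig, render_roi_traces, simulate_events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def traces18(rng):
    """Small random-but-valid 18-ROI raw trace set."""
    F = 100.0 + 10.0 * rng.random((18, 64))
    return RoiTraceSet(F, list(ROI_ORDER_18), frame_interval_s=0.18)


@pytest.fixture
def norm9(rng):
    """A 9-ROI normalized trace set with 40 valid frames."""
    v = rng.random((9, 40))
    v = (v - v.min()) / (v.max() - v.min())
    return NormTraceSet(v, list(ROI_ORDER_9), 0.18, 16)


@pytest.fixture(scope="session")
def short_sim():
    """A short low-noise simulation shared by read-only tests."""
    config = SimConfig(n_frames=512)
    truth = simulate_events(config, seed=7)
    traces, activity = render_roi_traces(truth, config, seed=7)
    return config, truth, traces, activity
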