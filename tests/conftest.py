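import numpy as np
import pytest

from zfbehave import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tail_bout_params():
    """One 20 Hz, 0.5 s bout inside a 0.7 s noiseless recording."""
    return synth.TailSimParams(duration=0.7,
                               bouts=[(0.1, 0.5, 20.0, 25.0)],
                               noise_sd=0.0, seed=7)


@pytest.fixture
def tail_trace(tail_bout_params):
    return synth.gen_tail_trace(tail_bout_params)


@pytest.fixture
def escape_track():
    params = synth.TrackSimParams(duration=30.0, frame_rate=25.0,
                                  tap_times=[10.0, 14.0, 18.0, 22.0, 26.0],
                                  escape_peak_accel=500.0,
                                  accel_duration=0.2, seed=11)
    return synth.gen_centroid_track(params)
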