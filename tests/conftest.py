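import numpy as np
import pytest

import openarms as oa


@pytest.fixture
def zm_spec():
    return oa.ArenaSpec.zero_maze()


@pytest.fixture
def of_spec():
    return oa.ArenaSpec.open_field(side=40.0)


@pytest.fixture
def traj_factory():
    """Build a Trajectory from coordinate arrays at a given rate."""

    def make(x, y, rate=25.0, arena=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return oa.Trajectory(times=np.arange(len(x)) / rate, x=x, y=y,
                             sample_rate=rate, arena=arena)

    return make


@pytest.fixture
def zone_factory(zm_spec):
    """Build a ZoneSeries from a label sequence at a given rate."""

    def make(labels, rate=25.0, arena=None):
        labels = np.asarray(labels)
        return oa.ZoneSeries(times=np.arange(len(labels)) / rate,
                             zone=labels, arena=arena or zm_spec)

    return make


@pytest.fixture
def speed_factory():
    def make(values, rate=25.0, smoothing=0.0):
        values = np.asarray(values, dtype=float)
        return oa.SpeedSeries(times=np.arange(len(values)) / rate,
                              speed=values, smoothing_window=smoothing,
                              sample_rate=rate)

    return make
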