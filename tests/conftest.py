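import numpy as np
import pytest

from alphatag.core import (
    AnalysisBand,
    EpochSet,
    SensorLayout,
    build_neighbor_graph,
    standard_layout_64,
)


@pytest.fixture(scope="session")
def layout64():
    return standard_layout_64()


@pytest.fixture(scope="session")
def graph64(layout64):
    return build_neighbor_graph(layout64, 0.33)


@pytest.fixture
def grid_layout():
    """4x4 unit grid, 16 channels."""
    chans = [f"g{i}{j}" for i in range(4) for j in range(4)]
    pos = np.array([(i, j) for i in range(4) for j in range(4)], dtype=float)
    return SensorLayout(chans, pos)


@pytest.fixture
def toy_band():
    return AnalysisBand("toy", 35.5, 36.5, 400)


def make_epochs(
    data=None,
    n_trials=4,
    n_channels=3,
    sfreq=200.0,
    t0=-0.5,
    n_samples=400,
    condition=None,
    channels=None,
    behavior=None,
):
    """Small synthetic EpochSet for unit tests."""
    times = t0 + np.arange(n_samples) / sfreq
    if data is None:
        data = np.zeros((n_trials, n_channels, n_samples))
    n_trials = data.shape[0]
    if channels is None:
        channels = [f"ch{i}" for i in range(data.shape[1])]
    if condition is None:
        condition = ["visual_cue"] * n_trials
    return EpochSet(
        data=data,
        sfreq=sfreq,
        times=times,
        channels=channels,
        condition=condition,
        behavior=behavior,
    )


@pytest.fixture
def epochs_factory():
    return make_epochs
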