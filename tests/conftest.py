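import numpy as np
import pytest

from shapetrack.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """A fast 160×160 px movie config used across module tests."""
    return SimulationConfig(
        field_size_px=(160, 160),
        n_frames=8,
        n_round_cells=2,
        n_dendritic_cells=1,
        min_separation_um=25.0,
        n_fibers=40,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
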