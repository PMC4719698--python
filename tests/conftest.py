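import numpy as np
import pytest

from ihcquant import SegmentationParams, SimulationParams


@pytest.fixture
def params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture
def small_sim() -> SimulationParams:
    """A fast, fully featured simulation setting for unit tests."""
    return SimulationParams(
        tile_width=240,
        tile_height=160,
        n_b_cells=12,
        n_t_cells=25,
        cell_radius_mean=5.0,
        cell_radius_sd=1.0,
        seed=42,
    )


@pytest.fixture
def noiseless_sim(small_sim) -> SimulationParams:
    """Noise-free palettes on white: segmentation should be pixel-exact."""
    return small_sim.with_overrides(
        red_palette_sd=0.0, brown_palette_sd=0.0, noise_sd=0.0, background_mode="white"
    )
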