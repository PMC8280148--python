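import numpy as np
import pytest

from mscrit import (
    BranchingConfig,
    EventRaster,
    Recording,
    extract_avalanches,
    simulate_branching_raster,
)


def make_raster(counts, base_dt=0.004, threshold=None):
    counts = np.asarray(counts)
    return EventRaster(
        events=counts > 0,
        counts=counts,
        bin_width=base_dt,
        base_dt=base_dt,
        threshold=threshold,
    )


@pytest.fixture(scope="session")
def critical_raster():
    """Large low-drive critical branching raster shared across tests."""
    cfg = BranchingConfig(
        n_channels=64,
        n_bins=600_000,
        branching_ratio=1.0,
        drive_rate=0.005,
        seed=101,
    )
    raster, annotations = simulate_branching_raster(cfg)
    return raster, annotations


@pytest.fixture(scope="session")
def critical_avalanches(critical_raster):
    raster, _ = critical_raster
    return extract_avalanches(raster)


@pytest.fixture
def white_noise_recording():
    rng = np.random.default_rng(7)
    return Recording(rng.normal(size=(4, 50_000)), sampling_rate=250.0)
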