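import numpy as np
import pytest

import tofmix as tm
from tofmix.simulate import AcquisitionConfig, TimingModel, simulate_acquisition


@pytest.fixture(scope="session")
def bank():
    return tm.load_bgo_cherenkov_bank()


@pytest.fixture(scope="session")
def desk_scanner():
    return tm.RingScanner.desk_2d()


@pytest.fixture(scope="session")
def desk_grid():
    return tm.VoxelGrid.desk_2d()


@pytest.fixture(scope="session")
def nema_phantom():
    return tm.nema_iq_phantom()


@pytest.fixture(scope="session")
def nema_sim(nema_phantom, desk_scanner, desk_grid):
    """A small mixture-bank NEMA acquisition shared across recon tests."""
    config = AcquisitionConfig(
        phantom=nema_phantom,
        scanner=desk_scanner,
        grid=desk_grid,
        duration_s=5.0,
        timing_model=TimingModel.mixture_bank(),
        rng_seed=7,
    )
    return simulate_acquisition(config)


@pytest.fixture(scope="session")
def desk_sensitivity(desk_scanner, desk_grid):
    return tm.sensitivity_image(desk_scanner, desk_grid)
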