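import numpy as np
import pytest

from thzresidue.spectra import default_grid
from thzresidue.synthetic import GeneratorConfig, HyperCube, simulate_study


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def noise_free_cfg():
    return GeneratorConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def tiny_study():
    """Two small cubes per class; enough for extraction/count tests."""
    cfg = GeneratorConfig(cube_height=40, cube_width=40, seed=5)
    return simulate_study(cfg, replicates_per_class=2)


@pytest.fixture()
def constant_cube(grid):
    """Cube whose every pixel carries the same fixed spectrum."""
    spec = 0.1 + 0.05 * np.arange(len(grid))
    data = np.broadcast_to(spec, (20, 20, len(grid))).copy()
    mask = np.zeros((20, 20), dtype=bool)
    mask[4:16, 4:16] = True
    return HyperCube(data, grid, mask, true_class=2, seed=0)
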