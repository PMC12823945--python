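import numpy as np
import pytest

from itdispersion.diffusion import ConcentrationField, build_grid
from itdispersion.synthetic import NOISE_OFF, simulate_tracer_experiment


@pytest.fixture(scope="session")
def bounded_grid():
    """Default injection-centric solver domain: [-6, 59] cm at 0.1 cm."""
    return build_grid(-6.0, 59.0, 650)


@pytest.fixture(scope="session")
def wide_grid():
    """A wide symmetric domain whose boundaries stay unreached in short runs."""
    return build_grid(-40.0, 40.0, 800)


@pytest.fixture(scope="session")
def noise_free_record():
    """Noise-free synthetic tracer record at D = 7.4 cm^2/min, no drift."""
    return simulate_tracer_experiment(d_true=7.4, drift_velocity=0.0, noise=NOISE_OFF, seed=0)


@pytest.fixture(scope="session")
def wide_record(wide_grid):
    """Noise-free record on a wide domain: boundaries unreached, D = 2."""
    return simulate_tracer_experiment(
        d_true=2.0, drift_velocity=0.0, noise=NOISE_OFF, seed=0, grid=wide_grid
    )


@pytest.fixture
def gaussian_field(wide_grid):
    """Narrow Gaussian (sigma = 0.5 cm) single-frame concentration field."""
    x = wide_grid.cell_centers
    values = np.exp(-(x**2) / (2 * 0.5**2))
    return ConcentrationField(grid=wide_grid, times=np.array([0.0]), values=values)
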