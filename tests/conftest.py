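import numpy as np
import pytest

from dogedge import (
    GridRaster,
    LandscapeConfig,
    generate_landscape,
    housing_density_surface,
    populated_mask,
    surface_path_distance,
)


@pytest.fixture
def flat_dem():
    """5x5 flat DEM, cell 30 m, origin at (0, 150)."""
    return GridRaster(np.zeros((5, 5)), 0.0, 150.0, 30.0, "elevation_m")


@pytest.fixture(scope="session")
def default_landscape():
    """One default synthetic landscape shared by the slower statistical tests."""
    return generate_landscape(LandscapeConfig(seed=42))


@pytest.fixture(scope="session")
def default_surface(default_landscape):
    land = default_landscape
    pop = populated_mask(housing_density_surface(land.residences, land.dem))
    return surface_path_distance(land.dem, pop)
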